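"""File formats: MRC/CCP4 volumes, reflection tables, tilt-series stacks.

Volumes travel as MRC mode-2 (32-bit float) maps written through gemmi,
with the voxel size encoded in the cell header.  Reflection tables use the
plain-text format of :mod:`nanoxtal.reflections`.  Tilt series are stored
as an MRC stack plus a sidecar text file of (angle, acquisition index)
pairs.
"""

from __future__ import annotations

import numpy as np
import gemmi

from .reflections import ReflectionSet
from .sim_crystal import TiltSeries
from .volume import Volume

__all__ = ["read_volume", "write_volume", "read_reflections",
           "write_reflections", "read_tilt_series", "write_tilt_series"]


def write_volume(vol: Volume, path) -> None:
    """Write a volume as an MRC mode-2 map with voxel size in the header."""
    grid = gemmi.FloatGrid(np.ascontiguousarray(
        vol.grid.astype(np.float32)))
    n = vol.shape
    grid.unit_cell = gemmi.UnitCell(n[0] * vol.voxel_size,
                                    n[1] * vol.voxel_size,
                                    n[2] * vol.voxel_size, 90, 90, 90)
    grid.spacegroup = gemmi.find_spacegroup_by_name("P1")
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def read_volume(path) -> Volume:
    """Read an MRC/CCP4 map; mode-2 payload with uniform voxel size."""
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot read MRC map {path}: {exc}") from exc
    mode = m.header_i32(4)
    if mode != 2:
        raise ValueError(f"{path}: unsupported MRC mode {mode} "
                         "(only mode 2, 32-bit float, is handled)")
    arr = np.array(m.grid, copy=True).astype(float)
    cell = m.grid.unit_cell
    voxels = np.array([cell.a, cell.b, cell.c]) / np.array(arr.shape)
    if not np.allclose(voxels, voxels[0], rtol=1e-4):
        raise ValueError(f"{path}: anisotropic voxel size {voxels}")
    return Volume(arr, float(voxels[0]))


def write_reflections(rs: ReflectionSet, path) -> None:
    rs.write(path)


def read_reflections(path) -> ReflectionSet:
    return ReflectionSet.read(path)


def write_tilt_series(ts: TiltSeries, stack_path, angles_path) -> None:
    """MRC stack (images along the first axis) plus angle/order sidecar."""
    vol = Volume(ts.images, ts.voxel_size)
    write_volume(vol, stack_path)
    with open(angles_path, "w") as fh:
        fh.write("# angle_deg acquisition_index\n")
        for a, n in zip(ts.tilt_angles, ts.acquisition_index):
            fh.write(f"{a:.4f} {n}\n")


def read_tilt_series(stack_path, angles_path) -> TiltSeries:
    vol = read_volume(stack_path)
    angles, order = [], []
    with open(angles_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            a, n = line.split()
            angles.append(float(a))
            order.append(int(n))
    if len(angles) != vol.shape[0]:
        raise ValueError(f"{angles_path}: {len(angles)} angles for "
                         f"{vol.shape[0]} images")
    return TiltSeries(vol.grid, np.array(angles), np.array(order, dtype=int),
                      vol.voxel_size)
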