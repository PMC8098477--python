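"""Data-quality metrics: phase residual, intensity CC, map CC, completeness.

These reproduce the standard evaluation of recovered reflection data
against a reference computed directly from the atomic (or pseudo-atomic)
model: the intensity-weighted mean absolute phase residual R_ref,phi, the
Pearson correlation of log intensities, the real-space map correlation and
the completeness of the Friedel-unique (P1) or symmetry-reduced set.
"""

from __future__ import annotations

import numpy as np
import scipy.fft

from .angles import wrap_deg
from .origin_search import expand_to_p1, reduce_to_asu
from .reflections import ReflectionSet
from .symmetry import unique_reflections
from .volume import Volume

__all__ = ["phase_residual_ref", "intensity_cc", "map_cc", "completeness",
           "synthesize_map"]


def phase_residual_ref(rs: ReflectionSet, ref: ReflectionSet,
                       align_origins: bool = True) -> float:
    """Intensity-weighted mean |wrapped phase difference| over shared h (deg).

    Weights are the reference intensities, favoring the reflections that
    dominate the density map.  Because the space group admits several
    equivalent crystallographic origins (and continuous shifts along polar
    axes), the residual is by default minimized over the permissible origin
    shifts, making it invariant under any allowed-origin choice of ``rs``.
    """
    ia, ib = ref.common(rs)
    if len(ia) == 0:
        raise ValueError("no shared reflections")
    hkl = ref.hkl[ia]
    w = np.clip(ref.intensity[ia], 0, None)
    if w.sum() <= 0:
        w = np.ones_like(w)
    delta = wrap_deg(ref.phase[ia] - rs.phase[ib])
    if not align_origins:
        return float(np.sum(w * np.abs(delta)) / w.sum())
    shifts, free = ref.sg.permissible_origin_shifts()
    if free.any():
        # refine continuous components on a fine 1D grid per polar axis
        grids = [np.linspace(0, 1, 721, endpoint=False) if f else None
                 for f in free]
        cands = []
        for o in shifts:
            axes = [grids[ax] if free[ax] else np.array([o[ax]])
                    for ax in range(3)]
            mesh = np.array(np.meshgrid(*axes, indexing="ij"))
            cands.append(mesh.reshape(3, -1).T)
        shifts = np.vstack(cands)
    dev = np.abs(wrap_deg(delta[None, :] + 360.0 * (shifts @ hkl.T)))
    res = (dev * w[None, :]).sum(axis=1) / w.sum()
    return float(res.min())


def intensity_cc(rs: ReflectionSet, ref: ReflectionSet) -> float:
    """Pearson correlation of log intensities over shared reflections."""
    ia, ib = ref.common(rs)
    i1 = ref.intensity[ia]
    i2 = rs.intensity[ib]
    ok = (i1 > 0) & (i2 > 0)
    if ok.sum() < 3:
        raise ValueError("need at least 3 shared positive intensities")
    x = np.log(i1[ok])
    y = np.log(i2[ok])
    if x.std() == 0 or y.std() == 0:
        raise ValueError("degenerate intensity variance")
    return float(np.corrcoef(x, y)[0, 1])


def synthesize_map(rs: ReflectionSet, shape, expand_symmetry: bool = True
                   ) -> Volume:
    """Real-space unit-cell map from (sqrt(I), phase) by Fourier synthesis.

    The reflection set is expanded to the Friedel-complete P1 set first
    (when ``expand_symmetry``), amplitudes are sqrt(max(I, 0)).
    """
    data = expand_to_p1(rs) if expand_symmetry else rs
    F = np.zeros(shape, dtype=complex)
    dims = np.array(shape)
    amp = np.sqrt(np.clip(data.intensity, 0, None))
    coeff = amp * np.exp(1j * np.deg2rad(data.phase))
    for sign in (1, -1):
        idx = np.mod(sign * data.hkl, dims)
        np.add.at(F, (idx[:, 0], idx[:, 1], idx[:, 2]),
                  coeff if sign == 1 else coeff.conj())
    # crystallographic synthesis convention rho(x) = sum F(h) e^{-2pi i h.x}
    rho = scipy.fft.fftn(F).real / F.size
    voxel = float(np.mean(rs.cell.lengths / dims))
    return Volume(rho, voxel)


def map_cc(rs: ReflectionSet, ref_map: Volume) -> float:
    """Pearson correlation between the synthesized map and a reference map.

    The map is synthesized on the reference grid; the correlation runs over
    all unit-cell voxels.
    """
    syn = synthesize_map(rs, ref_map.shape)
    a = syn.grid.ravel()
    b = ref_map.grid.ravel()
    if a.std() == 0 or b.std() == 0:
        raise ValueError("degenerate map variance")
    return float(np.corrcoef(a, b)[0, 1])


def completeness(rs: ReflectionSet, d_min: float = 3.3,
                 mode: str = "P1") -> float:
    """Fraction of unique reflections observed to ``d_min``.

    ``mode='P1'``: denominator is the full Friedel-unique set (Friedel
    mates count once; missing-wedge reflections are *not* excluded from the
    denominator).  ``mode='sg'``: numerator and denominator are reduced to
    the asymmetric unit of the space group first.
    """
    full = unique_reflections(rs.cell, d_min)
    full = full[~rs.sg.is_absent(full)]
    observed = rs.select(rs.d() >= d_min - 1e-9)
    if mode == "P1":
        return len(observed) / len(full)
    if mode == "sg":
        ref_full = ReflectionSet(full, np.ones(len(full)),
                                 np.zeros(len(full)), rs.cell,
                                 rs.spacegroup)
        n_asu = len(reduce_to_asu(ref_full))
        n_obs = len(reduce_to_asu(observed)) if len(observed) else 0
        return n_obs / n_asu
    raise ValueError(f"unknown completeness mode {mode!r}")
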