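"""End-to-end pipeline: simulate -> preprocess -> index -> extract.

`run_pipeline` wires the stages in their canonical order (preprocessing,
spot finding, indexing, peak extraction) for one volume, with every stage
parameter recorded in a provenance log so any run can be reproduced from
its configuration and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .indexing import find_spots, index_lattice, refine_cell_symmetry
from .peak_extraction import (ExtractionConfig, collect_reflections,
                              extract_reflections)
from .preprocess import preprocess
from .reflections import ReflectionSet
from .sim_crystal import (build_crystal_density, generate_pseudo_structure,
                          project_tilt_series, random_rotation,
                          reconstruct_tomogram, rotate_volume,
                          damaged_tilt_series)
from .symmetry import UnitCell
from .volume import Volume

__all__ = ["PipelineConfig", "PipelineResult", "simulate_tomogram",
           "run_pipeline"]


@dataclass
class PipelineConfig:
    """Parameters of the simulation + processing pipeline."""

    cell: tuple = (16.2, 29.1, 47.7, 90.0, 90.0, 90.0)
    spacegroup: str = "P212121"
    n_atoms: int = 4
    n_cells: tuple = (3, 3, 3)
    d_min: float = 3.0
    voxel: float = 1.0
    tilt_range: float = 60.0
    increment: float = 3.0
    taper_fraction: float = 0.5
    hits_per_image: int = 0
    extraction: dict = field(default_factory=dict)
    spot_sigma: float = 4.0
    min_spot_pixels: int = 2
    max_spot_pixels: int = 4000
    seed: int = 0
    tomogram: bool = True    # False: process the intact rotated volume

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Load a configuration from a YAML mapping; unknown keys error."""
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        valid = {f.name for f in
                 __import__("dataclasses").fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        for key in ("cell", "n_cells"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class PipelineResult:
    reflections: ReflectionSet
    solution: object
    n_spots: int
    n_accepted: int
    log: dict


def simulate_tomogram(cfg: PipelineConfig) -> tuple[Volume, np.ndarray]:
    """Simulated (possibly damaged) tomogram and the orientation used."""
    rng = np.random.default_rng(cfg.seed)
    cell = UnitCell(*cfg.cell)
    model = generate_pseudo_structure(int(rng.integers(2**31)), cfg.n_atoms,
                                      cell, cfg.spacegroup)
    crystal = build_crystal_density(model, cfg.n_cells, cfg.d_min, cfg.voxel)
    R = random_rotation(int(rng.integers(2**31)))
    oriented = rotate_volume(crystal, R)
    if not cfg.tomogram:
        return oriented, R
    if cfg.hits_per_image > 0:
        ts = damaged_tilt_series(oriented, cfg.hits_per_image,
                                 cfg.tilt_range, cfg.increment,
                                 seed=int(rng.integers(2**31)))
    else:
        ts = project_tilt_series(oriented, cfg.tilt_range, cfg.increment)
    return reconstruct_tomogram(ts, depth=oriented.shape[2]), R


def run_pipeline(cfg: PipelineConfig, volume: Volume | None = None
                 ) -> PipelineResult:
    """Process a tomogram (simulated when ``volume`` is None) to reflections.

    Stages: taper + center + Fourier transform; spot finding; 1D-FFT
    indexing with symmetry-constrained cell refinement; peak prediction and
    extraction; tabulation.  Raises RuntimeError naming the failing stage.
    """
    log = {"config": asdict(cfg)}
    if volume is None:
        volume, R = simulate_tomogram(cfg)
        log["orientation"] = R.tolist()
    try:
        fv, shift = preprocess(volume, cfg.taper_fraction)
        log["centering_shift"] = [int(s) for s in shift]
    except Exception as exc:
        raise RuntimeError(f"stage 'preprocess' failed: {exc}") from exc
    try:
        spots = find_spots(fv, d_limits=(None, cfg.d_min * 0.9),
                           pixel_limits=(cfg.min_spot_pixels,
                                         cfg.max_spot_pixels),
                           sigma_strong=cfg.spot_sigma)
        log["n_spots"] = len(spots)
        if len(spots) < 20:
            raise ValueError(f"only {len(spots)} spots found")
    except Exception as exc:
        raise RuntimeError(f"stage 'findspots' failed: {exc}") from exc
    try:
        sol = index_lattice(spots, voxel_size=volume.voxel_size,
                            grid_shape=fv.shape)
        sol = refine_cell_symmetry(sol, cfg.spacegroup, spots=spots)
        log["cell"] = [sol.cell.a, sol.cell.b, sol.cell.c,
                       sol.cell.alpha, sol.cell.beta, sol.cell.gamma]
    except Exception as exc:
        raise RuntimeError(f"stage 'index' failed: {exc}") from exc
    try:
        ecfg = ExtractionConfig(d_min=cfg.d_min, **cfg.extraction)
        observations = extract_reflections(fv, sol, ecfg, cfg.tilt_range,
                                           cfg.increment)
        rs = collect_reflections(observations, sol.cell, cfg.spacegroup)
        log["n_predicted"] = len(observations)
        log["n_accepted"] = len(rs)
        log["rejections"] = _rejection_counts(observations)
    except Exception as exc:
        raise RuntimeError(f"stage 'extract' failed: {exc}") from exc
    return PipelineResult(rs, sol, len(spots), len(rs), log)


def _rejection_counts(observations) -> dict:
    counts: dict[str, int] = {}
    for o in observations:
        key = "accepted" if o.accepted else (o.reason or "unknown")
        counts[key] = counts.get(key, 0) + 1
    return counts


def save_log(log: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(log, fh, indent=2, default=str)
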