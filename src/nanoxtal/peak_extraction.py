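"""Bragg-peak intensity and phase extraction from the Fourier volume.

Tomographic sampling leaves each Bragg peak only partially measured (the
data lie on skew central slices separated by the tilt increment), so no
generic reflection profile can be assumed.  Extraction therefore follows a
heuristic per-reflection pipeline:

1.  pixels brighter than mean + 4 sigma of the surrounding spherical
    subvolume are assigned to the peak (the contiguous set nearest the
    predicted position);
2.  reflections whose observed centroid strays more than 2 reciprocal
    pixels from the prediction are rejected -- such partial peaks
    frequently carry phases off by 180 degrees;
3.  the background under the peak is estimated by trilinear interpolation
    from unmasked neighbors (the mask also covers contiguous pixels above
    mean + 2 sigma) and subtracted;
4.  pixels are iteratively discarded until the intensity-weighted circular
    phase spread falls below 15 degrees;
5.  the reflection intensity is the sum of background-subtracted pixel
    intensities and its phase the intensity-weighted circular mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage

from .angles import weighted_phase_stats, wrap_deg
from .indexing import IndexingSolution
from .reflections import ReflectionSet
from .symmetry import unique_reflections
from .volume import FourierVolume

__all__ = ["ExtractionConfig", "PeakObservation", "predict_peaks",
           "extract_peak", "extract_reflections", "collect_reflections",
           "weighted_phase_stats"]


@dataclass
class ExtractionConfig:
    """Thresholds of the peak-extraction heuristic."""

    radius: int = 7             # subvolume radius in reciprocal voxels
    peak_sigma: float = 4.0     # assignment threshold above subvolume mean
    background_sigma: float = 2.0  # masking threshold for background
    centroid_tol: float = 2.0   # max centroid-prediction distance (voxels)
    phase_std_max: float = 15.0  # max intensity-weighted phase spread (deg)
    d_min: float = 3.0          # high-resolution limit in A

    def __post_init__(self):
        if min(self.radius, self.peak_sigma, self.background_sigma,
               self.centroid_tol, self.phase_std_max, self.d_min) <= 0:
            raise ValueError("all extraction parameters must be positive")
        if self.peak_sigma <= self.background_sigma:
            raise ValueError("peak_sigma must exceed background_sigma")


@dataclass
class PeakObservation:
    """Result of extracting one predicted reflection."""

    hkl: tuple
    intensity: float = 0.0
    phase: float = 0.0
    centroid: np.ndarray | None = None
    n_pixels: int = 0
    tilt_angle: float = float("nan")
    accepted: bool = False
    reason: str = ""


def predict_peaks(sol: IndexingSolution, d_min: float,
                  tilt_range: float = 60.0):
    """Predicted reciprocal-voxel positions of all reflections to d_min.

    Returns a list of (hkl, position, in_wedge).  The missing wedge is the
    region whose angular coordinate about the tilt (x) axis exceeds the
    tilt range; (0, 0, 0) is never predicted.
    """
    H = unique_reflections(sol.cell, d_min)
    pos = sol.position_of(H)
    center = np.array([n // 2 for n in sol.grid_shape])
    rel = pos - center
    psi = np.rad2deg(np.arctan2(rel[:, 2], rel[:, 1]))
    psi = np.where(psi > 90.0, psi - 180.0, psi)
    psi = np.where(psi <= -90.0, psi + 180.0, psi)
    on_axis = (np.abs(rel[:, 1]) < 1e-9) & (np.abs(rel[:, 2]) < 1e-9)
    psi = np.where(on_axis, 0.0, psi)
    in_wedge = np.abs(psi) > tilt_range
    return [(tuple(h), p, bool(w)) for h, p, w in zip(H, pos, in_wedge)]


def _sphere_mask(radius: int) -> np.ndarray:
    r = np.arange(-radius, radius + 1)
    x, y, z = np.meshgrid(r, r, r, indexing="ij")
    return x**2 + y**2 + z**2 <= radius**2


def _trilinear_background(inten: np.ndarray, mask: np.ndarray,
                          valid: np.ndarray) -> np.ndarray:
    """Estimate masked values from the nearest unmasked voxel per axis
    direction (inverse-distance weighted); subvolume mean as fallback."""
    bg = inten.copy()
    free = valid & ~mask
    if not free.any():
        return np.full_like(inten, inten[valid].mean() if valid.any() else 0)
    fallback = inten[free].mean()
    shape = inten.shape
    masked_idx = np.argwhere(mask & valid)
    for ix, iy, iz in masked_idx:
        vals, wts = [], []
        for ax, sgn in ((0, 1), (0, -1), (1, 1), (1, -1), (2, 1), (2, -1)):
            pos = [ix, iy, iz]
            dist = 0
            while True:
                pos[ax] += sgn
                dist += 1
                if not 0 <= pos[ax] < shape[ax]:
                    break
                if free[tuple(pos)]:
                    vals.append(inten[tuple(pos)])
                    wts.append(1.0 / dist)
                    break
        if vals:
            bg[ix, iy, iz] = np.average(vals, weights=wts)
        else:
            bg[ix, iy, iz] = fallback
    return bg


def extract_peak(fv: FourierVolume, hkl, pred, cfg: ExtractionConfig,
                 tilt_angle: float = float("nan")) -> PeakObservation:
    """Extract intensity and phase of one predicted reflection.

    See the module docstring for the pipeline.  Rejection reasons:
    "edge" (subvolume outside the grid), "no_peak" (nothing above the
    assignment threshold), "partial" (centroid too far from prediction) and
    "phase_incoherent" (fewer than 2 pixels survive the phase-spread rule).
    """
    obs = PeakObservation(hkl=tuple(hkl), tilt_angle=tilt_angle)
    r = cfg.radius
    p = np.asarray(pred, dtype=float)
    pi = np.round(p).astype(int)
    shape = np.array(fv.shape)
    if np.any(pi - r < 0) or np.any(pi + r + 1 > shape):
        obs.reason = "edge"
        return obs
    sl = tuple(slice(pi[ax] - r, pi[ax] + r + 1) for ax in range(3))
    inten = fv.intensity[sl]
    phase = fv.phase[sl]
    sphere = _sphere_mask(r)
    mean = inten[sphere].mean()
    std = inten[sphere].std()
    strong = (inten > mean + cfg.peak_sigma * std) & sphere
    if not strong.any():
        obs.reason = "no_peak"
        return obs
    labels, n_labels = scipy.ndimage.label(
        strong, structure=np.ones((3, 3, 3), dtype=int))
    local_pred = p - (pi - r)
    best_label, best_dist, best_com = 0, np.inf, None
    for lab in range(1, n_labels + 1):
        com = np.array(scipy.ndimage.center_of_mass(inten, labels, lab))
        dist = np.linalg.norm(com - local_pred)
        if dist < best_dist:
            best_label, best_dist, best_com = lab, dist, com
    peak_mask = labels == best_label
    obs.centroid = best_com + (pi - r)
    obs.n_pixels = int(peak_mask.sum())
    if best_dist > cfg.centroid_tol:
        obs.reason = "partial"
        return obs
    # background: mask peak plus contiguous moderately bright pixels
    moderate = (inten > mean + cfg.background_sigma * std) & sphere
    lab2, _ = scipy.ndimage.label(moderate | peak_mask,
                                  structure=np.ones((3, 3, 3), dtype=int))
    peak_labels = set(np.unique(lab2[peak_mask])) - {0}
    bg_mask = np.isin(lab2, list(peak_labels))
    background = _trilinear_background(inten, bg_mask, sphere)
    net = inten - background
    # phase-coherence refinement
    pix = np.argwhere(peak_mask)
    w = np.clip(net[peak_mask], 0, None)
    ph = phase[peak_mask]
    if w.sum() <= 0:
        w = inten[peak_mask]
    keep = np.ones(len(pix), dtype=bool)
    dropped = False
    while keep.sum() >= 2:
        m, s = weighted_phase_stats(ph[keep], w[keep])
        if s <= cfg.phase_std_max:
            break
        dev = np.abs(wrap_deg(ph - m)) * w
        dev[~keep] = -np.inf
        worst = np.flatnonzero(dev == dev.max())
        if len(worst) > 1:  # ties: drop the weaker pixel
            worst = worst[np.argsort(w[worst])]
        keep[worst[0]] = False
        dropped = True
    if keep.sum() < 2 and dropped:
        # outlier removal consumed the peak: phases never became coherent
        obs.reason = "phase_incoherent"
        return obs
    m, s = weighted_phase_stats(ph[keep], w[keep])
    if s > cfg.phase_std_max:
        obs.reason = "phase_incoherent"
        return obs
    obs.intensity = float(net[peak_mask][keep].sum())
    obs.phase = float(m)
    obs.n_pixels = int(keep.sum())
    obs.accepted = True
    return obs


def extract_reflections(fv: FourierVolume, sol: IndexingSolution,
                        cfg: ExtractionConfig | None = None,
                        tilt_range: float = 60.0,
                        increment: float = 3.0) -> list[PeakObservation]:
    """Predict and extract every reflection outside the missing wedge."""
    cfg = cfg or ExtractionConfig()
    out = []
    center = np.array([n // 2 for n in sol.grid_shape])
    for hkl, pos, in_wedge in predict_peaks(sol, cfg.d_min, tilt_range):
        if in_wedge:
            continue
        rel = pos - center
        psi = np.rad2deg(np.arctan2(rel[2], rel[1]))
        if psi > 90.0:
            psi -= 180.0
        elif psi <= -90.0:
            psi += 180.0
        tilt = float(np.clip(np.round(psi / increment) * increment,
                             -tilt_range, tilt_range))
        out.append(extract_peak(fv, hkl, pos, cfg, tilt_angle=tilt))
    return out


def collect_reflections(observations, cell, spacegroup: str = "P1"
                        ) -> ReflectionSet:
    """Tabulate accepted observations into a ReflectionSet.

    Duplicate Miller indices (which should not occur within one tomogram)
    are averaged with a warning.
    """
    rows: dict[tuple, list] = {}
    for o in observations:
        if not o.accepted:
            continue
        rows.setdefault(o.hkl, []).append(o)
    if not rows:
        return ReflectionSet(np.zeros((0, 3), dtype=int), np.zeros(0),
                             np.zeros(0), cell, spacegroup,
                             np.zeros(0, dtype=int), np.zeros(0))
    dupes = [h for h, v in rows.items() if len(v) > 1]
    if dupes:
        import warnings
        warnings.warn(f"duplicate observations for {len(dupes)} "
                      "reflections; averaging")
    hkl = np.array(sorted(rows), dtype=int)
    inten = np.empty(len(hkl))
    phase = np.empty(len(hkl))
    tilt = np.empty(len(hkl))
    for i, h in enumerate(hkl):
        group = rows[tuple(h)]
        ivals = np.array([o.intensity for o in group])
        pvals = np.array([o.phase for o in group])
        inten[i] = ivals.mean()
        wts = np.clip(ivals, 0, None)
        if wts.sum() <= 0:
            wts = np.ones_like(wts)
        phase[i] = weighted_phase_stats(pvals, wts)[0]
        tilt[i] = group[0].tilt_angle
    return ReflectionSet(hkl, inten, phase, cell, spacegroup, tilt=tilt)
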