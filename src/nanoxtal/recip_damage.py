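"""Reciprocal-space radiation-damage simulator and tilt-spread diagnostics.

Rather than damaging a density volume, this module damages reflection data
directly, which makes completeness, phase error and the angular spread of
reflections independently tunable.  For a randomly oriented crystal every
reflection is assigned to the nearest tilt image of a dose-symmetric scheme
(or discarded in the missing wedge); its intensity decays with a B factor
growing linearly with the image number n,

    I(h) = I0(h) * exp(-(n * B_rel) * q^2 / 4),      q = 1/d  [1/A],

the brightest reflections are retained to reach a target completeness, the
phase origin receives a random fractional shift and Gaussian phase noise is
added.  The Jensen-Shannon distance between the recorded tilt-angle
histogram and a uniform distribution over +/-60 degrees quantifies how
unevenly the surviving reflections cover the tilt range -- the quantity that
best predicts whether two data sets can be merged onto a common origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .angles import wrap_deg
from .merging import merge_datasets, merge_error, origin_alignment
from .origin_search import find_crystallographic_origin
from .reflections import ReflectionSet
from .sim_crystal import (dose_symmetric_order, generate_pseudo_structure,
                          random_rotation, structure_factors,
                          tilt_scheme_angles)
from .symmetry import UnitCell

__all__ = ["RecipDamageConfig", "assign_tilt", "simulate_damaged_dataset",
           "js_distance", "merging_success_sweep", "summarize_sweep",
           "origin_shift_success"]


@dataclass
class RecipDamageConfig:
    """Conditions for one simulated damaged data set."""

    b_rel: float = 0.0              # relative B factor, A^2 per image
    target_completeness: float = 0.3  # fraction of the Friedel-unique set
    phase_error_mean: float = 0.0   # mean |phase error| in degrees
    tilt_range: float = 60.0        # +/- degrees
    increment: float = 3.0          # degrees between images
    d_min: float = 3.3              # high-resolution limit in A
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 < self.target_completeness <= 1.0:
            raise ValueError("target completeness must lie in (0, 1]")
        if self.b_rel < 0 or self.phase_error_mean < 0:
            raise ValueError("B factor and phase error must be >= 0")


def assign_tilt(hkl, cell: UnitCell, orientation, tilt_range: float = 60.0,
                increment: float = 3.0, slice_half_width: float | None = None):
    """Recording tilt angle and image number for each reflection.

    The crystal's reciprocal vectors are rotated into the lab frame (tilt
    axis x, beam z); a reflection belongs to the central slice whose tilt
    angle is nearest the angular coordinate psi = atan2(s_z, s_y) folded
    into (-90, 90].  Reflections with |psi| beyond the tilt range fall in
    the missing wedge; those farther than ``slice_half_width`` (default:
    half the increment, i.e. a gap-free scheme) from every slice are
    unsampled.

    Returns (angle, n, status, psi) arrays; angle and n are NaN / 0 where
    status is "wedge" or "unsampled".  ``psi`` is the continuous angular
    coordinate of the reflection (its exact recording tilt), which is what
    tilt-distribution diagnostics should histogram -- the quantized slice
    angle would produce an artificial comb structure at 1 degree binning.
    """
    H = np.atleast_2d(np.asarray(hkl, dtype=float))
    s = (np.asarray(orientation) @ (cell.recip_matrix() @ H.T)).T
    psi = np.rad2deg(np.arctan2(s[:, 2], s[:, 1]))
    psi = np.where(psi > 90.0, psi - 180.0, psi)
    psi = np.where(psi <= -90.0, psi + 180.0, psi)
    on_axis = (np.abs(s[:, 1]) < 1e-12) & (np.abs(s[:, 2]) < 1e-12)
    psi = np.where(on_axis, 0.0, psi)
    if slice_half_width is None:
        slice_half_width = increment / 2.0
    angles = tilt_scheme_angles(tilt_range, increment)
    order = dose_symmetric_order(angles)
    nearest_idx = np.clip(np.round((psi + tilt_range) / increment), 0,
                          len(angles) - 1).astype(int)
    nearest = angles[nearest_idx]
    status = np.full(len(H), "ok", dtype=object)
    status[np.abs(psi) > tilt_range] = "wedge"
    gap = (np.abs(psi - nearest) > slice_half_width + 1e-12) \
        & (status == "ok")
    status[gap] = "unsampled"
    angle = np.where(status == "ok", nearest, np.nan)
    n = np.where(status == "ok", order[nearest_idx], 0)
    return angle, n.astype(int), status, psi


def simulate_damaged_dataset(reference: ReflectionSet,
                             cfg: RecipDamageConfig,
                             rng=None):
    """One damaged, incomplete, phase-shifted data set from true reflections.

    ``reference`` must contain the complete Friedel-unique set to the
    configured resolution with true intensities and phases on a
    crystallographic origin.  Returns (data, truth) where ``truth`` records
    the applied fractional shift ``u_true``, the orientation matrix and the
    per-reflection image numbers.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    R = random_rotation(rng)
    keep_d = reference.d() >= cfg.d_min - 1e-9
    ref = reference.select(keep_d)
    n_total = len(ref)
    angle, n, status, psi = assign_tilt(ref.hkl, ref.cell, R,
                                        cfg.tilt_range, cfg.increment)
    ok = status == "ok"
    decayed = ref.intensity[ok] * np.exp(
        -(n[ok] * cfg.b_rel) * ref.q()[ok] ** 2 / 4.0)
    n_keep = int(round(cfg.target_completeness * n_total))
    if n_keep > ok.sum():
        raise ValueError(
            f"target completeness {cfg.target_completeness:.2f} unreachable; "
            f"max achievable is {ok.sum() / n_total:.3f}")
    order = np.argsort(decayed)[::-1][:n_keep]
    sel = np.flatnonzero(ok)[order]
    u_true = rng.random(3)
    sigma = cfg.phase_error_mean * np.sqrt(np.pi / 2.0)
    noise = rng.normal(0.0, sigma, size=n_keep) if sigma > 0 else 0.0
    phase = wrap_deg(ref.phase[sel] - 360.0 * (ref.hkl[sel] @ u_true)
                     + noise)
    data = ReflectionSet(ref.hkl[sel], decayed[order], phase, ref.cell,
                         ref.spacegroup, tilt=psi[sel])
    truth = {"u_true": u_true, "orientation": R, "n": n[sel],
             "slice_angle": angle[sel], "n_total": n_total}
    return data, truth


# ---------------------------------------------------------------------------
# Jensen-Shannon tilt-spread diagnostic
# ---------------------------------------------------------------------------

def js_distance(tilt_angles, reference_range: float = 60.0,
                bin_width: float = 1.0) -> float:
    """JS distance between the tilt histogram and uniform +/-reference_range.

    The recorded tilt angles are binned at ``bin_width`` (default 1 degree)
    over the reference range; the score is the square root of the
    Jensen-Shannon divergence (base-2 logarithms) between the normalized
    histogram p and the uniform distribution q, so it lies in [0, 1] and
    vanishes only for a perfectly even spread over the full range.  Data
    spanning a narrower range than the reference are penalized even when
    internally uniform.
    """
    t = np.asarray(tilt_angles, dtype=float)
    t = t[np.isfinite(t)]
    if t.size == 0:
        raise ValueError("no recorded tilt angles")
    edges = np.arange(-reference_range, reference_range + bin_width / 2,
                      bin_width)
    # place angles exactly on the upper boundary into the last bin
    counts, _ = np.histogram(np.clip(t, -reference_range,
                                     reference_range - 1e-9), bins=edges)
    p = counts / counts.sum()
    q = np.full(len(p), 1.0 / len(p))
    m = 0.5 * (p + q)
    div = 0.5 * (_kl(p, m) + _kl(q, m))
    return float(np.sqrt(max(div, 0.0)))


def _kl(p, m) -> float:
    """Kullback-Leibler divergence with base-2 logs and 0 log 0 = 0."""
    mask = p > 0
    return float(np.sum(p[mask] * np.log2(p[mask] / m[mask])))


# ---------------------------------------------------------------------------
# merging-success study
# ---------------------------------------------------------------------------

#: Fractional merge-error threshold for a correctly found origin,
#: corresponding to roughly twice a 0.2 A sampling interval on cells of a
#: few tens of Angstrom.
SUCCESS_TOL_FRAC = 0.03


def origin_shift_success(u_est, u_target, sg,
                         tol_frac: float = SUCCESS_TOL_FRAC) -> bool:
    """Is an estimated shift within ``tol_frac`` of a valid target origin?

    The target is ``u_target`` modulo the space group's permissible origin
    shifts (discrete set plus polar axes, along which any component is
    valid); the distance is the minimal-image Euclidean norm in fractional
    coordinates.
    """
    shifts, free = sg.permissible_origin_shifts()
    d = np.asarray(u_est, dtype=float)[None, :] - (
        (np.asarray(u_target, dtype=float)[None, :] + shifts) % 1.0)
    d = (d + 0.5) % 1.0 - 0.5
    d[:, free] = 0.0
    return bool(np.linalg.norm(d, axis=1).min() < tol_frac)


DEFAULT_SYSTEMS = (
    (UnitCell(16.2, 29.1, 47.7, 90.0, 90.0, 90.0), "P212121"),
)


def merging_success_sweep(systems=DEFAULT_SYSTEMS,
                          completeness_values=(0.1, 0.2, 0.3, 0.4),
                          phase_error_values=(0.0, 10.0, 20.0, 30.0, 40.0),
                          b_rel_values=(0.0, 1.0, 3.0, 10.0),
                          pairs_per_condition: int = 3,
                          seed: int = 0,
                          interval: float = 0.2,
                          d_min: float = 3.3,
                          tilt_range: float = 60.0,
                          increment: float = 3.0,
                          n_atoms: int = 6,
                          run_origin_searches: bool = True) -> pd.DataFrame:
    """Monte-Carlo study of merging success across damage conditions.

    For every (system, completeness, phase error, B factor) condition,
    ``pairs_per_condition`` pairs of damaged data sets in independent random
    orientations with independent origin shifts are generated.  Each pair is
    aligned onto a common origin; optionally, the crystallographic origin is
    also searched for each individual set and for the merged pair.  Success
    means landing within twice the sampling interval of the appropriate true
    origin.  Returns one row per pair.
    """
    rng = np.random.default_rng(seed)
    tol = SUCCESS_TOL_FRAC
    rows = []
    for cell, sg_symbol in systems:
        model = generate_pseudo_structure(int(rng.integers(2**31)), n_atoms,
                                          cell, sg_symbol)
        reference = structure_factors(model, d_min)
        sg = reference.sg
        for comp in completeness_values:
            for perr in phase_error_values:
                for b_rel in b_rel_values:
                    cfg = RecipDamageConfig(
                        b_rel=b_rel, target_completeness=comp,
                        phase_error_mean=perr, tilt_range=tilt_range,
                        increment=increment, d_min=d_min)
                    for _ in range(pairs_per_condition):
                        row = _run_pair(reference, cfg, rng, interval, tol,
                                        sg, run_origin_searches)
                        if row is None:
                            continue
                        row.update({"system": sg_symbol,
                                    "completeness": comp,
                                    "phase_error": perr, "b_rel": b_rel})
                        rows.append(row)
    return pd.DataFrame(rows)


def _run_pair(reference, cfg, rng, interval, tol, sg, run_origin_searches):
    try:
        ds1, truth1 = simulate_damaged_dataset(reference, cfg, rng)
        ds2, truth2 = simulate_damaged_dataset(reference, cfg, rng)
    except ValueError:
        return None  # completeness unreachable under this wedge
    js1 = js_distance(ds1.tilt)
    js2 = js_distance(ds2.tilt)
    row = {"js_mean": 0.5 * (js1 + js2), "js_1": js1, "js_2": js2,
           "n_1": len(ds1), "n_2": len(ds2)}
    u_true_pair = (truth2["u_true"] - truth1["u_true"]) % 1.0
    try:
        u_est, resid = origin_alignment(ds1, ds2, interval=interval)
    except ValueError:
        return None
    ia, _ = ds1.common(ds2)
    row["n_shared"] = len(ia)
    row["merge_error"] = merge_error(u_est, u_true_pair)
    row["residual"] = resid
    row["success_common"] = row["merge_error"] < tol
    if run_origin_searches:
        ok_single = []
        for ds, truth in ((ds1, truth1), (ds2, truth2)):
            res = find_crystallographic_origin(ds, interval=interval)
            ok_single.append(origin_shift_success(
                res.shift, -truth["u_true"], sg, tol))
        row["success_single_1"], row["success_single_2"] = ok_single
        merged, _ = merge_datasets([ds1, ds2], interval=interval)
        res_m = find_crystallographic_origin(merged, interval=interval)
        row["success_merged"] = origin_shift_success(
            res_m.shift, -truth1["u_true"], sg, tol)
    return row


def summarize_sweep(table: pd.DataFrame) -> dict:
    """Success rates (%) and the pairwise-vs-single / merged-vs-single gaps."""
    out = {
        "common_origin_pct": 100.0 * table["success_common"].mean(),
    }
    if "success_single_1" in table:
        singles = pd.concat([table["success_single_1"],
                             table["success_single_2"]])
        out["single_set_origin_pct"] = 100.0 * singles.mean()
        out["merged_origin_pct"] = 100.0 * table["success_merged"].mean()
        out["common_minus_single_pct"] = (out["common_origin_pct"]
                                          - out["single_set_origin_pct"])
        out["merged_minus_single_pct"] = (out["merged_origin_pct"]
                                          - out["single_set_origin_pct"])
    return out
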