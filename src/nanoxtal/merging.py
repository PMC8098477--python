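"""Phase-origin alignment, intensity scaling and greedy merging of data sets.

Phases from different crystals can only be averaged once the data sets share
a phase origin.  Shifting the origin of a data set by the fractional cell
vector u changes each phase according to the translation theorem,

    phi_u(h) = phi(h) - 360 * (h . u)    [degrees],

so the shift relating two data sets is found by an exhaustive search over a
real-space grid of fractional positions (default spacing 0.2 A per cell
axis), minimizing the intensity-weighted mean absolute wrapped residual
between the reference phases and the shifted phases of the second data set.
Intensities are origin-independent and are placed on a common scale with a
Debye-Waller style log-linear model.  Data sets are merged greedily in the
order that maximizes the number of reflections shared with the growing
reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._gridscore import grid_resultant_score
from .angles import wrap_deg, weighted_circular_mean
from .reflections import ReflectionSet

__all__ = ["phase_shift", "origin_grid", "origin_alignment",
           "ScalingParams", "scale_intensities", "merge_datasets",
           "merge_error"]


def phase_shift(rs: ReflectionSet, u) -> ReflectionSet:
    """Shift the phase origin of a reflection set by fractional vector u."""
    u = np.asarray(u, dtype=float)
    out = rs.copy()
    out.phase = wrap_deg(out.phase - 360.0 * (out.hkl @ u))
    return out


def origin_grid(cell, interval: float = 0.2) -> tuple[np.ndarray, ...]:
    """Per-axis fractional search positions with ~``interval`` A spacing."""
    if interval <= 0:
        raise ValueError("interval must be positive")
    dims = [max(1, int(round(L / interval))) for L in cell.lengths]
    return tuple(np.arange(n) / n for n in dims), tuple(dims)


def _pair_weights(i1, i2, mode: str) -> np.ndarray:
    i1 = np.clip(np.asarray(i1, dtype=float), 0, None)
    i2 = np.clip(np.asarray(i2, dtype=float), 0, None)
    if mode == "geometric":
        return np.sqrt(i1 * i2)
    if mode == "arithmetic":
        return 0.5 * (i1 + i2)
    raise ValueError(f"unknown weight mode {mode!r}")


def _wrapped_residual_grid(hkl, delta_deg, weights, dims, candidates,
                           residual_mode: str = "squared") -> np.ndarray:
    """Exact weighted wrapped residual (deg) at fractional candidates.

    ``squared`` returns the root of the weighted mean squared wrapped
    difference (the default; it localizes the minimum better under heavy
    phase noise), ``absolute`` the weighted mean absolute difference.
    """
    w = np.asarray(weights, dtype=float)
    wsum = w.sum()
    phase = np.abs(wrap_deg(delta_deg[None, :]
                            - 360.0 * (candidates @ hkl.T)))
    if residual_mode == "squared":
        return np.sqrt(np.sum(w[None, :] * phase**2, axis=1) / wsum)
    if residual_mode == "absolute":
        return np.sum(w[None, :] * phase, axis=1) / wsum
    raise ValueError(f"unknown residual mode {residual_mode!r}")


def _cosine_score_fft(hkl, delta_deg, weights, dims) -> np.ndarray:
    """Resultant score C(u) = sum_h w_h cos(delta_h - 360 h.u) on the grid.

    C is maximal where the absolute residual is minimal and is used to
    shortlist candidates for exact evaluation.  Evaluated for every grid
    node at once by a zoom DFT over the occupied Miller-index box.
    """
    return grid_resultant_score(hkl, weights * np.exp(
        1j * np.deg2rad(delta_deg)), dims)


def _grid_candidates_from_indices(flat_idx, dims) -> np.ndarray:
    ijk = np.array(np.unravel_index(flat_idx, dims)).T
    return ijk / np.array(dims)


def _tie_break(candidates: np.ndarray, residuals: np.ndarray,
               tol: float = 1e-9) -> int:
    """Index of the best candidate: lowest residual, then smallest
    minimal-image |u|, then lexicographic order."""
    best = residuals.min()
    tied = np.flatnonzero(residuals <= best + tol)
    if len(tied) == 1:
        return int(tied[0])
    uu = candidates[tied]
    d = np.linalg.norm(np.minimum(uu, 1.0 - uu), axis=1)
    order = np.lexsort((uu[:, 2], uu[:, 1], uu[:, 0], np.round(d, 12)))
    return int(tied[order[0]])


def origin_alignment(ref: ReflectionSet, other: ReflectionSet,
                     interval: float = 0.2, weight_mode: str = "geometric",
                     method: str = "auto", shortlist: int = 1024,
                     residual_mode: str = "squared"
                     ) -> tuple[np.ndarray, float]:
    """Find the fractional shift placing ``other`` on the origin of ``ref``.

    Searches the fractional-cell grid for the u minimizing the
    intensity-weighted wrapped residual between

        wrap(phi_ref(h) - phi_other(h) - 360 h.u)

    over the shared reflections, with w_h the geometric mean of the two
    observed intensities and the residual either root-mean-square
    (``residual_mode='squared'``, default) or mean absolute
    (``'absolute'``).  The returned u satisfies
    ``other approx phase_shift(ref, u)``; apply ``phase_shift(other, -u)``
    to move ``other`` onto the reference origin.

    ``method='grid'`` evaluates every node exhaustively (the reference
    oracle); ``'auto'`` uses an FFT resultant score to shortlist candidates
    and evaluates the exact residual only on those.

    Returns (u, residual_deg).
    """
    ia, ib = ref.common(other)
    if len(ia) == 0:
        raise ValueError("disjoint reflection sets: no shared reflections")
    if len(ia) < 3:
        raise ValueError("need at least 3 shared reflections")
    hkl = ref.hkl[ia]
    if np.linalg.matrix_rank(hkl) < 3:
        import warnings
        warnings.warn("shared reflections are coplanar; origin shift is "
                      "ill-determined along one axis")
    delta = wrap_deg(ref.phase[ia] - other.phase[ib])
    w = _pair_weights(ref.intensity[ia], other.intensity[ib], weight_mode)
    if w.sum() <= 0:
        w = np.ones_like(w)
    fracs, dims = origin_grid(ref.cell, interval)
    n_nodes = int(np.prod(dims))
    if method == "grid" or (method == "auto" and n_nodes <= 4096):
        mesh = np.array(np.meshgrid(*fracs, indexing="ij"))
        candidates = mesh.reshape(3, -1).T
        res = _wrapped_residual_grid(hkl, delta, w, dims, candidates,
                                     residual_mode)
    else:
        score = _cosine_score_fft(hkl, delta, w, dims)
        k = min(shortlist, n_nodes)
        flat = np.argpartition(score.ravel(), -k)[-k:]
        candidates = _grid_candidates_from_indices(flat, dims)
        res = _wrapped_residual_grid(hkl, delta, w, dims, candidates,
                                     residual_mode)
    best = _tie_break(candidates, res)
    return candidates[best].copy(), float(res[best])


@dataclass
class ScalingParams:
    """Debye-Waller relative scaling: log(I2/I1) ~ b + m q - q^2 sigma^2 / 2."""

    m: float
    b: float
    sigma: float
    curvature: float = 0.0   # raw fitted coefficient of q^2 (= sigma^2/2)


def scale_intensities(ref: ReflectionSet, other: ReflectionSet
                      ) -> tuple[ScalingParams, ReflectionSet]:
    """Scale ``other`` onto the intensity scale of ``ref``.

    Fits ``ln I_other - ln I_ref = b + m q - q^2 sigma^2 / 2`` by linear
    least squares over the shared reflections with positive intensities
    (logarithmic residuals keep the fit stable across decades of intensity),
    then divides the model out of ``other``.
    """
    ia, ib = ref.common(other)
    i1 = ref.intensity[ia]
    i2 = other.intensity[ib]
    ok = (i1 > 0) & (i2 > 0)
    if ok.sum() < 5:
        raise ValueError("need at least 5 shared reflections with positive "
                         "intensities for scaling")
    q = np.atleast_1d(ref.cell.q_of(ref.hkl[ia][ok]))
    y = np.log(i2[ok]) - np.log(i1[ok])
    X = np.column_stack([np.ones_like(q), q, -0.5 * q**2])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    b, m, s2 = coef
    params = ScalingParams(m=float(m), b=float(b),
                           sigma=float(np.sqrt(max(s2, 0.0))),
                           curvature=float(s2))
    qa = other.q()
    model = b + m * qa - 0.5 * s2 * qa**2
    scaled = other.copy()
    scaled.intensity = scaled.intensity * np.exp(-model)
    return params, scaled


def merge_datasets(sets, interval: float = 0.2, weight_mode: str = "geometric",
                   method: str = "auto", scale: bool = True
                   ) -> tuple[ReflectionSet, list[np.ndarray]]:
    """Greedy merge of reflection sets onto the origin of the first set.

    At each step the unmerged set sharing the most reflections with the
    current reference is aligned (origin search), optionally scaled, and its
    observations pooled.  The final phase per reflection is the
    intensity-weighted circular mean over observations, the intensity the
    plain mean, and the multiplicity the observation count.  All reflections
    are treated as symmetry-unrelated (P1) during merging.

    Returns the merged set and the list of per-step origin shifts.
    """
    sets = list(sets)
    if len(sets) < 2:
        raise ValueError("need at least 2 sets to merge")
    obs: dict[tuple, list] = {}

    def add_observations(rs: ReflectionSet):
        for i, h in enumerate(rs.hkl):
            obs.setdefault(tuple(h), []).append(
                (rs.intensity[i], rs.phase[i], rs.tilt[i]))

    def current_reference(template: ReflectionSet) -> ReflectionSet:
        hkl = np.array(sorted(obs), dtype=int)
        inten = np.empty(len(hkl))
        phase = np.empty(len(hkl))
        mult = np.empty(len(hkl), dtype=int)
        tilt = np.empty(len(hkl))
        for i, h in enumerate(hkl):
            rows = obs[tuple(h)]
            ivals = np.array([r[0] for r in rows])
            pvals = np.array([r[1] for r in rows])
            inten[i] = ivals.mean()
            wts = np.clip(ivals, 0, None)
            if wts.sum() <= 0:
                wts = np.ones_like(wts)
            phase[i] = weighted_circular_mean(pvals, wts)
            mult[i] = len(rows)
            tilt[i] = rows[0][2]
        return ReflectionSet(hkl, inten, phase, template.cell,
                             template.spacegroup, mult, tilt)

    add_observations(sets[0])
    remaining = list(range(1, len(sets)))
    shifts: list[np.ndarray] = []
    deferred_rounds = 0
    while remaining:
        reference = current_reference(sets[0])
        shared_counts = []
        for j in remaining:
            ia, _ = reference.common(sets[j])
            shared_counts.append(len(ia))
        pick = int(np.argmax(shared_counts))
        if shared_counts[pick] == 0:
            deferred_rounds += 1
            if deferred_rounds > len(remaining):
                raise ValueError(
                    f"data set(s) {remaining} share no reflections with the "
                    "reference and cannot be merged")
            remaining.append(remaining.pop(0))
            continue
        deferred_rounds = 0
        j = remaining.pop(pick)
        nxt = sets[j]
        u, _ = origin_alignment(reference, nxt, interval=interval,
                                weight_mode=weight_mode, method=method)
        aligned = phase_shift(nxt, -u)
        if scale:
            try:
                _, aligned = scale_intensities(reference, aligned)
            except ValueError:
                pass  # too few positive shared pairs; merge unscaled
        add_observations(aligned)
        shifts.append(u)
    return current_reference(sets[0]), shifts


def merge_error(u_est, u_true) -> float:
    """Minimal-image Euclidean distance between fractional origin shifts."""
    d = np.asarray(u_est, dtype=float) - np.asarray(u_true, dtype=float)
    d = (d + 0.5) % 1.0 - 0.5
    return float(np.linalg.norm(d))
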