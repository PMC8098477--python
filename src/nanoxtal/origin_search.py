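"""Crystallographic phase-origin location and asymmetric-unit reduction.

A merged data set sits on an arbitrary common origin; its phases only obey
the space-group phase relations once shifted to a crystallographic origin.
Each node of a fractional-cell grid is scored as a candidate origin with
three metrics:

* the intensity-weighted residual between symmetry-equivalent phase
  estimates and their circular mean,
* the intensity-weighted distance of centric phases from their two allowed
  values (omitted when the data contain no centrics), and
* the negative skew of a symmetry-averaged density map synthesized from
  (sqrt(I), shifted phases) -- protein maps are positively skewed while
  wrongly phased maps are Gaussian.

The metrics are z-score normalized across candidates and summed with equal
weight; the candidate with the lowest combined score wins.  The search is
hierarchical: an FFT-based resultant score ranks every grid node, the exact
phase metrics are evaluated on a shortlist, and the (costlier) map skew on
the best few hundred of those.  An exhaustive mode evaluating the exact
metrics at every node is available for small grids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.fft

from ._gridscore import grid_resultant_score
from .angles import wrap_deg, weighted_circular_mean
from .merging import origin_grid, phase_shift, _tie_break
from .reflections import ReflectionSet

__all__ = ["symmetry_mean_phase", "symmetry_phase_residual",
           "centric_residual", "map_skew", "find_crystallographic_origin",
           "reduce_to_asu", "expand_to_p1", "OriginSearchResult"]


# ---------------------------------------------------------------------------
# symmetry-equivalent phase estimates
# ---------------------------------------------------------------------------

def _equivalent_estimates(rs: ReflectionSet):
    """Precompute per-reflection symmetry-equivalent phase estimates.

    For each stored reflection h (the target) and each operation s, the
    equivalent index g = h R_s carries the target's phase through

        phi(h) = phi(g) + 360 h . t_s,           g = h R_s,

    and after an origin shift u each estimate becomes A - 360 (g . u) where
    A is the transported phase at u = 0.  Friedel mates are used when only
    -g is stored.  Returns flat arrays (group, A_deg, g_vec, weight) where
    ``group`` indexes the target reflection; estimates whose source row and
    phase offset duplicate an earlier one for the same target are dropped.
    """
    sg = rs.sg
    index = rs.index_map()
    groups, A, G, W, SRC = [], [], [], [], []
    heq, dphi = sg.equivalents(rs.hkl)   # heq[i,s] = h_i R_s
    # phi(h_i) = phi(heq[i,s]) - dphi[i,s]  since phi(hR) = phi(h) + dphi
    for i in range(len(rs)):
        seen = set()
        for s in range(sg.n_ops):
            g = tuple(heq[i, s])
            row = index.get(g)
            sign = 1.0
            if row is None:
                row = index.get(tuple(-np.array(g)))
                sign = -1.0
                if row is None:
                    continue
            a = wrap_deg(sign * rs.phase[row] - dphi[i, s])
            key = (row, round(float(wrap_deg(dphi[i, s])) * sign, 6), sign)
            if key in seen:
                continue
            seen.add(key)
            groups.append(i)
            A.append(a)
            G.append(heq[i, s])
            W.append(max(rs.intensity[row], 0.0))
            SRC.append(row)
    return (np.array(groups, dtype=int), np.array(A, dtype=float),
            np.array(G, dtype=int).reshape(-1, 3), np.array(W, dtype=float),
            np.array(SRC, dtype=int))


def symmetry_mean_phase(rs: ReflectionSet, hkl, u=(0, 0, 0)) -> float:
    """Mean phase of reflection ``hkl`` estimated from observed equivalents.

    Every observed symmetry-equivalent of hkl is transported to an estimate
    of phi(hkl) (including Friedel mates) at origin shift u; the result is
    their intensity-weighted circular mean.
    """
    u = np.asarray(u, dtype=float)
    target = np.asarray(hkl, dtype=int)
    sg = rs.sg
    index = rs.index_map()
    heq, dphi = sg.equivalents(target[None, :])
    ests, wts = [], []
    for s in range(sg.n_ops):
        g = heq[0, s]
        row = index.get(tuple(g))
        sign = 1.0
        if row is None:
            row = index.get(tuple(-g))
            sign = -1.0
            if row is None:
                continue
        a = sign * rs.phase[row] - dphi[0, s]
        ests.append(wrap_deg(a - 360.0 * (g @ u)))
        wts.append(max(rs.intensity[row], 0.0))
    if not ests:
        raise ValueError(f"no observed equivalents for reflection {hkl}")
    w = np.array(wts)
    if w.sum() <= 0:
        w = np.ones_like(w)
    return weighted_circular_mean(np.array(ests), w)


def symmetry_phase_residual(rs: ReflectionSet, u=(0, 0, 0)) -> float:
    """Intensity-weighted mean deviation of equivalents from their mean (deg).

    Raises ValueError when the data contain no symmetry-related information
    (P1, or no equivalents observed), in which case the metric is
    uninformative and excluded from combined scoring.
    """
    group, A, G, W, _ = _equivalent_estimates(rs)
    res = _sym_residual_at(group, A, G, W,
                           np.asarray(u, dtype=float)[None, :])
    if np.isnan(res[0]):
        raise ValueError("no symmetry-related phase information in data")
    return float(res[0])


def _sym_residual_at(group, A, G, W, candidates) -> np.ndarray:
    """Exact symmetry residual (deg) at each candidate shift (K, 3).

    Estimates are grouped by target reflection (``group`` is sorted); the
    group-wise circular means are accumulated with segment sums.
    """
    n_groups = group.max() + 1 if len(group) else 0
    if n_groups == 0:
        return np.full(len(candidates), np.nan)
    counts = np.bincount(group, minlength=n_groups)
    multi = counts[group] >= 2
    if not np.any(multi):
        return np.full(len(candidates), np.nan)
    group = group[multi]
    A, G, W = A[multi], G[multi], W[multi]
    w = np.where(W > 0, W, 1e-12)
    candidates = np.asarray(candidates, dtype=float)
    out = np.empty(len(candidates))
    starts = np.flatnonzero(np.r_[True, np.diff(group) != 0])
    pos_of_group = np.cumsum(np.r_[False, np.diff(group) != 0])
    # single precision is ample for ranking candidates; exact evaluations
    # of a handful of shifts keep double precision
    ztype = np.complex64 if len(candidates) > 16 else np.complex128
    chunk = max(1, int(2e7) // max(len(A), 1))
    for lo in range(0, len(candidates), chunk):
        cand = candidates[lo:lo + chunk]
        est = A[:, None] - 360.0 * (G @ cand.T)        # (n_est, K)
        z = (w[:, None] * np.exp(1j * np.deg2rad(est))).astype(ztype)
        gsum = np.add.reduceat(z, starts, axis=0)
        mean = np.rad2deg(np.angle(gsum))              # (n_seg, K)
        dev = np.abs(wrap_deg(est - mean[pos_of_group]))
        out[lo:lo + chunk] = w @ dev / w.sum()
    return out


# ---------------------------------------------------------------------------
# centric restrictions
# ---------------------------------------------------------------------------

def _centric_data(rs: ReflectionSet):
    cen = rs.sg.is_centric(rs.hkl)
    if not np.any(cen):
        return None
    hkl = rs.hkl[cen]
    theta = rs.sg.centric_allowed_phase(hkl)
    w = np.clip(rs.intensity[cen], 0, None)
    return hkl, np.asarray(theta, dtype=float), rs.phase[cen], w


def _wrap180(x):
    return (np.asarray(x, dtype=float) + 90.0) % 180.0 - 90.0


def centric_residual(rs: ReflectionSet, u=(0, 0, 0)) -> float:
    """Intensity-weighted distance of centric phases to allowed values (deg).

    Allowed phases for a centric reflection are theta_h modulo 180; the
    distance is the wrapped offset folded into (-90, 90].  Returns NaN when
    the data contain no centric reflections (metric omitted).
    """
    data = _centric_data(rs)
    if data is None:
        return float("nan")
    hkl, theta, phase, w = data
    res = _centric_residual_at(hkl, theta, phase, w,
                               np.asarray(u, dtype=float)[None, :])
    return float(res[0])


def _centric_residual_at(hkl, theta, phase, w, candidates) -> np.ndarray:
    ww = np.where(w > 0, w, 1e-12)
    phi_u = phase[:, None] - 360.0 * (hkl @ candidates.T)
    dev = np.abs(_wrap180(phi_u - theta[:, None]))
    return np.sum(ww[:, None] * dev, axis=0) / ww.sum()


# ---------------------------------------------------------------------------
# map skew
# ---------------------------------------------------------------------------

def _skew_machinery(rs: ReflectionSet, grid_d: float):
    """Sparse scatter operators for symmetry-averaged map synthesis.

    The symmetrized structure factors F_sym(g) = (1/N) sum_s F_u(g R_s)
    e^{2 pi i g.t_s} are linear in the per-reflection coefficients
    F_u(h), so the scatter onto the synthesis grid (plus Friedel
    completion) is encoded once as two sparse matrices, applied to F_u and
    to its conjugate respectively.
    """
    from scipy.sparse import csr_matrix

    sg = rs.sg
    dims = tuple(int(2 * np.ceil(1.5 * L / grid_d)) for L in rs.cell.lengths)
    rot_inv = [np.round(np.linalg.inv(R)).astype(int) for R in sg.rotations]
    n = int(np.prod(dims))
    dims_arr = np.array(dims)
    src_p, idx_p, fac_p = [], [], []
    src_c, idx_c, fac_c = [], [], []
    for Ri, t in zip(rot_inv, sg.translations):
        g = rs.hkl @ Ri                      # output indices with g R_s = h
        ph = np.exp(2j * np.pi * (g @ t))
        gg = np.mod(g, dims_arr)
        src_p.append(np.arange(len(rs)))
        idx_p.append(np.ravel_multi_index((gg[:, 0], gg[:, 1], gg[:, 2]),
                                          dims))
        fac_p.append(ph)
        gg = np.mod(-g, dims_arr)
        src_c.append(np.arange(len(rs)))
        idx_c.append(np.ravel_multi_index((gg[:, 0], gg[:, 1], gg[:, 2]),
                                          dims))
        fac_c.append(ph.conj())
    S_plus = csr_matrix((np.concatenate(fac_p),
                         (np.concatenate(src_p), np.concatenate(idx_p))),
                        shape=(len(rs), n), dtype=np.complex64)
    S_conj = csr_matrix((np.concatenate(fac_c),
                         (np.concatenate(src_c), np.concatenate(idx_c))),
                        shape=(len(rs), n), dtype=np.complex64)
    return dims, S_plus, S_conj


def _map_skews(rs: ReflectionSet, candidates, grid_d: float) -> np.ndarray:
    """Skew of the symmetry-averaged density map at each candidate shift."""
    dims, S_plus, S_conj = _skew_machinery(rs, grid_d)
    amp = np.sqrt(np.clip(rs.intensity, 0, None))
    phase0 = np.deg2rad(rs.phase)
    candidates = np.asarray(candidates, dtype=float)
    out = np.empty(len(candidates))
    n = int(np.prod(dims))
    chunk = max(1, int(4e7) // n)
    for lo in range(0, len(candidates), chunk):
        cands = candidates[lo:lo + chunk]
        coeff = (amp[None, :] * np.exp(
            1j * (phase0[None, :]
                  - 2.0 * np.pi * (cands @ rs.hkl.T)))).astype(np.complex64)
        grids = np.asarray(coeff @ S_plus) + np.asarray(coeff.conj() @ S_conj)
        rho = scipy.fft.ifftn(grids.reshape((len(cands),) + dims),
                              axes=(1, 2, 3)).real
        rho = rho.reshape(len(cands), -1)
        mu = rho.mean(axis=1, keepdims=True)
        d = rho - mu
        m2 = np.mean(d * d, axis=1)
        m3 = np.mean(d * d * d, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[lo:lo + chunk] = np.where(m2 > 0, m3 / m2**1.5, 0.0)
    return out


def map_skew(rs: ReflectionSet, u=(0, 0, 0), grid_d: float = 3.3) -> float:
    """Negative skew of the symmetry-averaged map at origin shift u.

    The map is synthesized from amplitudes sqrt(max(I, 0)) and the shifted
    phases on a grid of spacing ~``grid_d / 3`` and averaged over the
    space-group operations; the negative of the third standardized moment is
    returned so that lower values indicate more probable origins.
    """
    if len(rs) < 10:
        raise ValueError("need at least 10 reflections for a skew map")
    s = _map_skews(rs, np.asarray(u, dtype=float)[None, :], grid_d)
    return float(-s[0])


# ---------------------------------------------------------------------------
# combined origin search
# ---------------------------------------------------------------------------

@dataclass
class OriginSearchResult:
    """Outcome of the crystallographic-origin search."""

    shift: np.ndarray                 # best fractional origin shift
    scores: pd.DataFrame              # evaluated candidates with metrics
    note: str = ""


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = np.nanstd(x)
    if not np.isfinite(sd) or sd == 0:
        return np.zeros_like(x)
    return (x - np.nanmean(x)) / sd


def find_crystallographic_origin(rs: ReflectionSet, interval: float = 0.2,
                                 grid_d: float | None = None,
                                 shortlist: int = 1024,
                                 skew_candidates: int = 256,
                                 use_skew: bool = True) -> OriginSearchResult:
    """Locate the fractional shift placing ``rs`` on a crystallographic origin.

    The returned shift u is such that ``phase_shift(rs, u)`` obeys the
    space-group phase relations.  For P1 every origin is crystallographic
    and (0, 0, 0) is returned.

    The search grid has ~``interval`` A spacing per axis.  Every node is
    ranked with FFT resultant scores of the two phase metrics; the exact
    metrics are computed for the ``shortlist`` best nodes, the map skew for
    the ``skew_candidates`` best of those, and each available metric is
    z-score normalized over the evaluated candidates before the equal-weight
    sum is minimized.
    """
    sg = rs.sg
    if sg.n_ops == 1:
        return OriginSearchResult(
            np.zeros(3), pd.DataFrame(), note="P1: any origin is valid")
    fracs, dims = origin_grid(rs.cell, interval)
    n_nodes = int(np.prod(dims))
    group, A, G, W, _ = _equivalent_estimates(rs)
    counts = np.bincount(group) if len(group) else np.array([])
    have_sym = len(group) > 0 and np.any(counts[group] >= 2)
    cen = _centric_data(rs)

    cheap = np.zeros(dims)
    if have_sym:
        cheap += _zscore(_sym_pair_score(group, A, G, W, dims)).reshape(dims)
    if cen is not None:
        cheap += _zscore(_centric_score(cen, dims)).reshape(dims)
    if not have_sym and cen is None:
        raise ValueError("data carry no symmetry or centric phase "
                         "information; cannot locate an origin")
    k = min(shortlist, n_nodes)
    flat = np.argpartition(cheap.ravel(), -k)[-k:]
    ijk = np.array(np.unravel_index(flat, dims)).T
    candidates = ijk / np.array(dims)

    cols = {"u1": candidates[:, 0], "u2": candidates[:, 1],
            "u3": candidates[:, 2]}
    combined = np.zeros(len(candidates))
    if have_sym:
        sym = _sym_residual_at(group, A, G, W, candidates)
        cols["sym_residual"] = sym
        combined += _zscore(sym)
    if cen is not None:
        cres = _centric_residual_at(*cen, candidates)
        cols["centric_residual"] = cres
        combined += _zscore(cres)
    cols["neg_skew"] = np.full(len(candidates), np.nan)
    if use_skew and len(rs) >= 10:
        m = min(skew_candidates, len(candidates))
        top = np.argsort(combined)[:m]
        negskew = -_map_skews(rs, candidates[top],
                              grid_d or _default_grid_d(rs))
        cols["neg_skew"] = np.full(len(candidates), np.nan)
        np.put(cols["neg_skew"], top, negskew)
        final = combined[top] + _zscore(negskew)
        best_local = _tie_break(candidates[top], final)
        best = int(top[best_local])
        combined_full = combined.copy()
        combined_full[top] = final
        cols["combined"] = combined_full
    else:
        cols["combined"] = combined
        best = _tie_break(candidates, combined)
    scores = pd.DataFrame(cols)
    return OriginSearchResult(candidates[best].copy(), scores)


def _default_grid_d(rs: ReflectionSet) -> float:
    d = rs.d()
    return float(np.min(d[np.isfinite(d)]))


def _sym_pair_score(group, A, G, W, dims) -> np.ndarray:
    """Resultant score for the symmetry residual on the full grid.

    For each pair of estimates (i, j) of the same reflection the deviation
    wrap(A_i - A_j - 360 (g_i - g_j) . u) is small at good origins, so
    sum_{ij} w_ij cos(...) is a zoom DFT over coefficients at g_i - g_j.
    """
    order = np.argsort(group, kind="stable")
    group, A, G, W = group[order], A[order], G[order], W[order]
    starts = np.flatnonzero(np.r_[True, np.diff(group) != 0])
    ends = np.r_[starts[1:], len(group)]
    hkl, coeffs = [], []
    for s, e in zip(starts, ends):
        for i in range(s, e):
            for j in range(i + 1, e):
                w = np.sqrt(max(W[i], 1e-12) * max(W[j], 1e-12))
                hkl.append(G[i] - G[j])
                coeffs.append(w * np.exp(1j * np.deg2rad(A[i] - A[j])))
    if not hkl:
        return np.zeros(int(np.prod(dims)))
    return grid_resultant_score(np.array(hkl), np.array(coeffs),
                                dims).ravel()


def _centric_score(cen, dims) -> np.ndarray:
    """Resultant score for the centric residual on the full grid.

    dist(phi_u, theta mod 180) is minimal when cos(2 (phi_u - theta)) is
    maximal; coefficients w e^{2i(phi - theta)} are placed at 2h.
    """
    hkl, theta, phase, w = cen
    coeffs = (np.where(w > 0, w, 1e-12)
              * np.exp(2j * np.deg2rad(phase - theta)))
    return grid_resultant_score(2 * hkl, coeffs, dims).ravel()


# ---------------------------------------------------------------------------
# ASU reduction
# ---------------------------------------------------------------------------

def _asu_representative(sg, hkl):
    """Canonical representative and transported-phase bookkeeping.

    Among all h R_s and their Friedel mates, the lexicographically largest
    index is the representative.  Returns (rep, offset_deg, sign) such that
    phi(rep) = sign * phi(h) + offset.
    """
    heq, dphi = sg.equivalents(np.asarray(hkl, dtype=int)[None, :])
    best = None
    for s in range(sg.n_ops):
        g = heq[0, s]
        # phi(g) = phi(h) + dphi[0, s]
        for sign_vec, sign in ((g, 1.0), (-g, -1.0)):
            cand = tuple(int(x) for x in sign_vec)
            off = sign * dphi[0, s]
            key = cand
            if best is None or key > best[0]:
                best = (key, off, sign)
    return best


def reduce_to_asu(rs: ReflectionSet, u=(0, 0, 0)) -> ReflectionSet:
    """Shift by u, then merge symmetry-equivalents onto ASU representatives.

    Phases are transported through the space-group phase relations (and
    negated for Friedel mates), then combined by intensity-weighted circular
    mean; intensities are averaged and multiplicities summed.  Requires the
    data to sit on a crystallographic origin for the phase average to be
    meaningful.
    """
    shifted = phase_shift(rs, u) if np.any(np.asarray(u, dtype=float)) \
        else rs
    sg = rs.sg
    pooled: dict[tuple, list] = {}
    for i in range(len(shifted)):
        rep, off, sign = _asu_representative(sg, shifted.hkl[i])
        phase = wrap_deg(sign * shifted.phase[i] + off)
        pooled.setdefault(rep, []).append(
            (shifted.intensity[i], phase, shifted.multiplicity[i],
             shifted.tilt[i]))
    hkl = np.array(sorted(pooled), dtype=int)
    inten = np.empty(len(hkl))
    phs = np.empty(len(hkl))
    mult = np.empty(len(hkl), dtype=int)
    tilt = np.empty(len(hkl))
    for i, h in enumerate(hkl):
        rows = pooled[tuple(h)]
        ivals = np.array([r[0] for r in rows])
        pvals = np.array([r[1] for r in rows])
        wts = np.clip(ivals, 0, None)
        if wts.sum() <= 0:
            wts = np.ones_like(wts)
        inten[i] = ivals.mean()
        phs[i] = weighted_circular_mean(pvals, wts)
        mult[i] = sum(r[2] for r in rows)
        tilt[i] = rows[0][3]
    return ReflectionSet(hkl, inten, phs, rs.cell, rs.spacegroup, mult, tilt)


def expand_to_p1(rs: ReflectionSet) -> ReflectionSet:
    """Expand ASU data to the full Friedel-unique P1 set by symmetry."""
    sg = rs.sg
    heq, dphi = sg.equivalents(rs.hkl)
    pooled: dict[tuple, tuple] = {}
    for i in range(len(rs)):
        for s in range(sg.n_ops):
            g = heq[i, s]
            ph = wrap_deg(rs.phase[i] + dphi[i, s])
            for cand, sign in ((g, 1.0), (-g, -1.0)):
                first = np.where(cand[0] != 0, cand[0],
                                 np.where(cand[1] != 0, cand[1], cand[2]))
                if first <= 0:
                    continue
                key = tuple(int(x) for x in cand)
                if key not in pooled:
                    pooled[key] = (rs.intensity[i], wrap_deg(sign * ph),
                                   rs.multiplicity[i], rs.tilt[i])
    hkl = np.array(sorted(pooled), dtype=int)
    data = [pooled[tuple(h)] for h in hkl]
    return ReflectionSet(hkl, np.array([d[0] for d in data]),
                         np.array([d[1] for d in data]), rs.cell,
                         rs.spacegroup,
                         np.array([d[2] for d in data], dtype=int),
                         np.array([d[3] for d in data]))
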