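"""Bragg-spot finding and lattice indexing in the tomogram's transform.

Spot finding scans the Fourier volume slice by slice along the x axis
(parallel to the tilt axis), thresholds bright pixels against local
mean/variance statistics, assembles contiguous bright pixels across slices
into 3D spots and filters them by resolution window and pixel count.

Indexing uses the 1D-FFT directions method: candidate real-space lattice
directions are sampled on a hemisphere, spot centroids are projected onto
each direction and the periodicity of the projections is scored by a 1D
FFT.  The strongest mutually non-coplanar candidate vectors form the
reciprocal-basis matrix A mapping Miller indices to reciprocal-voxel
coordinates, refined by least squares against the assigned spots and
optionally constrained by the known space-group symmetry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft
import scipy.ndimage

from .symmetry import UnitCell, space_group
from .volume import FourierVolume

__all__ = ["Spot", "IndexingSolution", "find_spots", "index_lattice",
           "refine_cell_symmetry"]


@dataclass
class Spot:
    """A connected bright region in the Fourier volume."""

    centroid: np.ndarray     # reciprocal voxel coords, relative to grid corner
    intensity: float
    n_pixels: int


@dataclass
class IndexingSolution:
    """Reciprocal basis A (Miller -> reciprocal voxel) and derived cell."""

    A: np.ndarray             # 3x3, columns are a*, b*, c* in voxel units
    cell: UnitCell
    spacegroup: str = "P1"
    voxel_size: float = 1.0   # real-space voxel (A), sets the A-to-1/A scale
    grid_shape: tuple = (0, 0, 0)

    def miller_of(self, centroids) -> np.ndarray:
        """Fractional Miller indices of reciprocal-voxel positions."""
        x = np.atleast_2d(centroids) - np.array(
            [n // 2 for n in self.grid_shape])
        return x @ np.linalg.inv(self.A).T

    def position_of(self, hkl) -> np.ndarray:
        """Reciprocal-voxel positions (absolute) of Miller indices."""
        h = np.atleast_2d(np.asarray(hkl, dtype=float))
        return h @ self.A.T + np.array([n // 2 for n in self.grid_shape])


def find_spots(fv: FourierVolume, gain: float = 1.0,
               d_limits: tuple = (None, None),
               pixel_limits: tuple = (3, 1000),
               sigma_strong: float = 4.0,
               window: int = 7,
               exclude_center: float = 3.5) -> list[Spot]:
    """Detect Bragg spots by per-slice dispersion thresholding.

    Along each x slice, a pixel is strong when its intensity exceeds the
    local mean by ``sigma_strong`` local standard deviations (both computed
    in a ``window``-sized box, scaled by ``gain``).  Strong pixels are
    merged across slices with 26-connectivity and filtered by the
    resolution window ``d_limits = (d_max, d_min)`` in Angstrom and by
    ``pixel_limits = (min, max)``.  The direct beam region within
    ``exclude_center`` voxels of the grid center is ignored.
    """
    if gain <= 0:
        raise ValueError("gain must be positive")
    inten = fv.intensity
    strong = np.zeros(inten.shape, dtype=bool)
    for x in range(inten.shape[0]):
        sl = inten[x]
        mean = scipy.ndimage.uniform_filter(sl, size=window)
        sqmean = scipy.ndimage.uniform_filter(sl * sl, size=window)
        var = np.clip(sqmean - mean * mean, 0, None)
        strong[x] = (sl - mean) > sigma_strong * np.sqrt(gain * var + 1e-30)
    labels, n_labels = scipy.ndimage.label(
        strong, structure=np.ones((3, 3, 3), dtype=int))
    if n_labels == 0:
        return []
    center = np.array([n // 2 for n in inten.shape])
    sums = scipy.ndimage.sum_labels(inten, labels, np.arange(1, n_labels + 1))
    coms = scipy.ndimage.center_of_mass(inten, labels,
                                        np.arange(1, n_labels + 1))
    counts = scipy.ndimage.sum_labels(np.ones_like(inten), labels,
                                      np.arange(1, n_labels + 1))
    spots = []
    qvox = fv.recip_voxel_size
    lo, hi = pixel_limits
    d_max, d_min = d_limits
    for i in range(n_labels):
        npix = int(counts[i])
        if npix < lo or npix > hi:
            continue
        com = np.array(coms[i])
        rel = com - center
        if np.linalg.norm(rel) <= exclude_center:
            continue
        q = np.linalg.norm(rel * qvox)
        if q <= 0:
            continue
        d = 1.0 / q
        if d_min is not None and d < d_min:
            continue
        if d_max is not None and d > d_max:
            continue
        spots.append(Spot(com, float(sums[i]), npix))
    spots.sort(key=lambda s: -s.intensity)
    return spots


# ---------------------------------------------------------------------------
# 1D-FFT indexing
# ---------------------------------------------------------------------------

def _hemisphere_directions(n: int = 4000) -> np.ndarray:
    """Quasi-uniform directions on the upper hemisphere (Fibonacci grid)."""
    i = np.arange(n) + 0.5
    z = i / n                      # upper hemisphere only
    phi = np.pi * (1 + 5**0.5) * i
    r = np.sqrt(1 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _direction_score(proj: np.ndarray, grid_n: int, span: float):
    """Periodicity score of projected centroids via a 1D FFT.

    The projections are binned onto ``grid_n`` points spanning [-span, span];
    the strongest non-DC Fourier magnitude is the score and its frequency
    gives the candidate real-space lattice vector length (in units of
    1 / reciprocal voxel).
    """
    hist = np.zeros(grid_n)
    idx = np.clip(((proj + span) / (2 * span) * grid_n).astype(int), 0,
                  grid_n - 1)
    np.add.at(hist, idx, 1.0)
    F = np.abs(scipy.fft.rfft(hist))
    k_min = 2  # skip DC and the slowest drift component
    k = k_min + int(np.argmax(F[k_min:]))
    freq = k / (2 * span)          # cycles per reciprocal-voxel unit
    return F[k], freq


def _refine_frequency(proj: np.ndarray, f0: float, df: float,
                      n_fine: int = 81) -> float:
    """Maximize |sum exp(2 pi i f p)| on a fine grid around f0.

    The coarse FFT bin spacing quantizes candidate lattice-vector lengths
    too coarsely for Miller rounding; this zoom step restores the length to
    a fraction of a percent.
    """
    f = np.linspace(f0 - df, f0 + df, n_fine)
    amp = np.abs(np.exp(2j * np.pi * np.outer(f, proj)).sum(axis=1))
    return float(f[np.argmax(amp)])


def _comb_amplitude(proj: np.ndarray, f: float) -> float:
    return float(np.abs(np.exp(2j * np.pi * f * proj).sum()))


def _fundamental(proj: np.ndarray, f: float, df: float,
                 accept: float = 0.7) -> float:
    """Replace a harmonic frequency by its fundamental when supported.

    The strongest FFT bin can be the m-th harmonic of the true lattice
    period; f/m is accepted when its (locally refined) comb amplitude is at
    least ``accept`` of the harmonic's.
    """
    base = _comb_amplitude(proj, f)
    for m in (3, 2):
        sub = _refine_frequency(proj, f / m, df)
        if _comb_amplitude(proj, sub) >= accept * base:
            return sub
    return f


def index_lattice(spots, cell_hint: UnitCell | None = None,
                  voxel_size: float = 1.0, grid_shape=None,
                  n_directions: int = 4000, n_candidates: int = 30,
                  max_spots: int = 150) -> IndexingSolution:
    """Determine the reciprocal basis from spot positions (1D-FFT method).

    ``spots`` may be Spot objects or an (N, 3) array of reciprocal-voxel
    centroids (absolute grid coordinates when ``grid_shape`` is given,
    otherwise already relative to the transform center).  The returned
    solution carries the basis in voxel units and the unit cell in Angstrom
    derived from ``voxel_size`` and ``grid_shape``.

    Raises ValueError("degenerate lattice") for coplanar/collinear input.
    """
    if len(spots) and isinstance(spots[0], Spot):
        # weak spots are often shape-transform sidelobes; index with the
        # strongest ones only
        ranked = sorted(spots, key=lambda s: -s.intensity)[:max_spots]
        cents = np.array([s.centroid for s in ranked])
        inten = np.array([s.intensity for s in ranked])
    else:
        cents = np.atleast_2d(np.asarray(spots, dtype=float))[:max_spots]
        inten = np.ones(len(cents))
    if grid_shape is not None:
        cents = cents - np.array([n // 2 for n in grid_shape])
    if len(cents) < 6:
        raise ValueError("too few spots to index")
    sv = np.linalg.svd(cents, compute_uv=False)
    if sv[2] < 0.02 * sv[0]:
        raise ValueError("degenerate lattice: spots are coplanar or "
                         "collinear")
    # scale to O(1) for numerical comfort
    span = np.max(np.linalg.norm(cents, axis=1)) * 1.05
    dirs = _hemisphere_directions(n_directions)
    proj = cents @ dirs.T                      # (n_spots, n_dirs)
    grid_n = 512
    scores = np.empty(len(dirs))
    freqs = np.empty(len(dirs))
    for j in range(len(dirs)):
        scores[j], freqs[j] = _direction_score(proj[:, j], grid_n, span)
    best = np.argsort(scores)[::-1]
    # collect candidate real-space vectors v = freq * direction, deduplicated
    candidates = []
    df = 1.0 / (2 * span)
    for j in best[:400]:
        f = _refine_frequency(proj[:, j], freqs[j], df)
        f = _fundamental(proj[:, j], f, df)
        v = f * dirs[j]
        if not candidates:
            candidates.append(v)
            continue
        dup = False
        for w in candidates:
            cosang = abs(v @ w) / (np.linalg.norm(v) * np.linalg.norm(w))
            if cosang > 0.98 and abs(np.linalg.norm(v) - np.linalg.norm(w)) \
                    < 0.1 * np.linalg.norm(w):
                dup = True
                break
        if not dup:
            candidates.append(v)
        if len(candidates) >= n_candidates:
            break
    basis = _pick_basis(candidates, cents)
    if basis is None:
        raise ValueError("degenerate lattice: candidate vectors are "
                         "coplanar or collinear")
    A = np.linalg.inv(basis)                   # columns: reciprocal basis
    A, resid = _refine_assignment(A, cents, inten)
    A = _primitivize(A, cents)
    A, resid = _refine_assignment(A, cents, inten)
    sol = IndexingSolution(A, _cell_from_A(A, voxel_size, grid_shape),
                           "P1", voxel_size,
                           tuple(grid_shape) if grid_shape is not None
                           else (0, 0, 0))
    return sol


def _vector_score(v, cents, tol: float = 0.15) -> float:
    """Fraction of spots whose projection on v is near-integer."""
    p = cents @ v
    return float((np.abs(p - np.round(p)) < tol).mean())


def _pick_basis(candidates, cents, min_volume: float = 1e-6):
    """Best-indexing triple of short, non-coplanar candidate vectors.

    Candidate real-space vectors are first scored individually by the
    fraction of spots they index (projections near-integer); spot lists
    from tomograms contain artifact spots, so triples are ranked by the
    fraction of spots they index jointly rather than by first success.
    """
    if len(candidates) < 3:
        return None
    scored = [(v, _vector_score(v, cents)) for v in candidates]
    good = [v for v, s in scored if s >= 0.6]
    if len(good) < 3:
        good = [v for v, s in sorted(scored, key=lambda t: -t[1])[:12]]
    good = sorted(good, key=np.linalg.norm)
    pool = good[:24]
    # short combination vectors of two axes can crowd out the only
    # candidate carrying the third direction; if the pool is nearly
    # coplanar, append the shortest clearly out-of-plane vectors
    if len(pool) >= 3 and len(good) > len(pool):
        sv, basis = np.linalg.svd(np.array(pool), compute_uv=True)[1:3]
        if sv[2] < 0.1 * sv[0]:
            normal = basis[2]
            extra = [v for v in good[len(pool):]
                     if abs(v @ normal) / np.linalg.norm(v) > 0.3]
            pool = pool + extra[:6]
    good = pool
    triples = []
    for i in range(len(good)):
        for j in range(i + 1, len(good)):
            if np.linalg.norm(np.cross(good[i], good[j])) < 1e-8:
                continue
            for k in range(j + 1, len(good)):
                B = np.array([good[i], good[j], good[k]])
                vol = abs(np.linalg.det(B))
                norms = np.prod(np.linalg.norm(B, axis=1))
                if vol < 0.05 * norms or vol < min_volume:
                    continue
                frac = cents @ B.T   # h_i = v_i . x for row vectors v_i
                dev = np.abs(frac - np.round(frac))
                indexed = float((dev.max(axis=1) < 0.2).mean())
                if indexed < 0.5:
                    continue
                triples.append(((round(indexed, 2), -vol), B))
    if not triples:
        return None
    triples.sort(key=lambda t: t[0], reverse=True)
    # a non-lattice combination can pass the loose test over a limited
    # index range; a refit followed by a tight test separates true bases
    # (which sharpen) from accidental ones (which cannot)
    best = None
    best_key = (-1.0, 0.0)
    for _, B in triples[:8]:
        A, _ = _refine_assignment(np.linalg.inv(B), cents)
        frac = cents @ np.linalg.inv(A).T
        dev = np.abs(frac - np.round(frac))
        tight = float((dev.max(axis=1) < 0.08).mean())
        key = (round(tight, 2), -abs(np.linalg.det(B)))
        if key > best_key:
            best_key = key
            best = B
    return best


def _primitivize(A: np.ndarray, cents: np.ndarray) -> np.ndarray:
    """Collapse a non-primitive basis onto the lattice the spots occupy.

    Any integer combination of the true real-space basis vectors indexes
    every spot, so the picked basis can describe a superlattice whose
    Miller assignments occupy only a sublattice of Z^3.  The Hermite
    normal form of the occupied index set reveals that sublattice; when
    its determinant exceeds 1 the basis is rewritten so the assignments
    become primitive.
    """
    from itertools import product as _product

    from sympy import Matrix
    from sympy.matrices.normalforms import hermite_normal_form

    for _ in range(3):  # repeat to catch composite indices (4, 9, ...)
        frac = cents @ np.linalg.inv(A).T
        m = np.round(frac).astype(int)
        keep = (np.abs(frac - m).max(axis=1) < 0.2) & np.any(m != 0, axis=1)
        if keep.sum() < 10:
            return A
        mk = m[keep]
        found = None
        # vote on congruences m.v = 0 (mod k): a majority of assignments
        # obeying one marks a sublattice (artifact spots break exact
        # integer-lattice computations, so voting replaces exact HNF)
        for k in (2, 3, 5):
            # accept a congruence when clearly above its chance level 1/k
            # (artifact spots dilute the vote, so demand 5 sigma + floor)
            thresh = max(0.7, 1.0 / k + 5.0 * np.sqrt(
                (1.0 / k) * (1 - 1.0 / k) / len(mk)))
            for v in _product(range(k), repeat=3):
                if v == (0, 0, 0):
                    continue
                if ((mk @ np.array(v)) % k == 0).mean() >= thresh:
                    found = (k, np.array(v))
                    break
            if found:
                break
        if found is None:
            return A
        k, v = found
        # basis of the sublattice {m : m.v = 0 mod k} via HNF of generators
        gens = [k * np.eye(3, dtype=int)[:, i] for i in range(3)]
        for i in range(3):
            for j in range(3):
                if i != j:
                    gens.append(v[j] * np.eye(3, dtype=int)[:, i]
                                - v[i] * np.eye(3, dtype=int)[:, j])
        G = Matrix(np.array(gens).T.tolist())
        try:
            H = hermite_normal_form(G)
        except Exception:
            return A
        Hc = np.array(H.tolist(), dtype=float)
        if Hc.shape != (3, 3) or abs(round(np.linalg.det(Hc))) <= 1:
            return A
        A = A @ Hc
        A, _ = _refine_assignment(A, cents)
    return A


def _refine_assignment(A, cents, weights=None):
    """Least-squares refinement of A against rounded Miller assignments.

    The acceptance tolerance tightens over iterations so artifact spots
    that accidentally index at a loose tolerance are shed; when provided,
    ``weights`` (spot intensities) down-weight weak artifact spots.
    """
    if weights is None:
        w = np.ones(len(cents))
    else:
        w = np.sqrt(np.clip(np.asarray(weights, dtype=float), 0, None))
        if w.sum() <= 0:
            w = np.ones(len(cents))
    for tol in (0.35, 0.3, 0.25, 0.2, 0.15):
        frac = cents @ np.linalg.inv(A).T
        m = np.round(frac)
        keep = np.all(np.abs(frac - m) < tol, axis=1) \
            & np.any(m != 0, axis=1)
        if keep.sum() < 6:
            break
        M = m[keep] * w[keep, None]
        X = cents[keep] * w[keep, None]
        A = np.linalg.lstsq(M, X, rcond=None)[0].T
    frac = cents @ np.linalg.inv(A).T
    resid = float(np.abs(frac - np.round(frac)).mean())
    return A, resid


def _cell_from_A(A, voxel_size: float, grid_shape) -> UnitCell:
    """Unit-cell parameters implied by a voxel-unit reciprocal basis."""
    if grid_shape is None:
        n = np.array([1.0, 1.0, 1.0])
        scale = 1.0
    else:
        n = np.array(grid_shape, dtype=float)
    Bstar = A / (n * voxel_size)[:, None]     # columns a*,b*,c* in 1/A
    real = np.linalg.inv(Bstar).T             # rows?? columns of inv^T
    a_vec, b_vec, c_vec = np.linalg.inv(Bstar)
    a, b, c = (np.linalg.norm(v) for v in (a_vec, b_vec, c_vec))

    def ang(u, v):
        return np.rad2deg(np.arccos(np.clip(
            u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1)))

    return UnitCell(a, b, c, ang(b_vec, c_vec), ang(a_vec, c_vec),
                    ang(a_vec, b_vec))


def indexing_residual(sol: IndexingSolution, cents) -> float:
    """Mean |fractional - rounded| Miller residual of centroids."""
    frac = sol.miller_of(cents)
    return float(np.abs(frac - np.round(frac)).mean())


def rebase_to_cell(sol: IndexingSolution, cell_hint: UnitCell,
                   max_index: int = 3, length_tol: float = 0.05,
                   angle_tol: float = 5.0) -> IndexingSolution:
    """Re-express the solution in the basis matching a known cell.

    Indexing determines the lattice only up to a unimodular change of
    basis; when the conventional cell is known, the integer combinations
    of the found real-space basis vectors matching the hint's lengths and
    angles are located and the reciprocal basis A is rewritten so Miller
    indices refer to the conventional cell.

    Raises ValueError when no matching basis exists (wrong lattice).
    """
    n = np.array(sol.grid_shape, dtype=float) if sol.grid_shape != (0, 0, 0) \
        else np.ones(3)
    Bstar = sol.A / (n * sol.voxel_size)[:, None]      # 1/A
    real = np.linalg.inv(Bstar)                        # rows a, b, c in A
    rng_i = range(-max_index, max_index + 1)
    combos = [np.array(c) for c in
              __import__("itertools").product(rng_i, rng_i, rng_i)
              if any(c)]
    targets = cell_hint.lengths
    cands = [[] for _ in range(3)]
    for m in combos:
        v = m @ real
        L = np.linalg.norm(v)
        for i, t in enumerate(targets):
            if abs(L - t) / t < length_tol:
                cands[i].append((m, v))
    t_ang = cell_hint.angles

    def ang(u, v):
        return np.rad2deg(np.arccos(np.clip(
            u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1)))

    best = None
    for ma, va in cands[0]:
        for mb, vb in cands[1]:
            if abs(ang(va, vb) - t_ang[2]) > angle_tol:
                continue
            for mc, vc in cands[2]:
                M = np.array([ma, mb, mc])
                if abs(round(np.linalg.det(M))) != 1:
                    continue
                if abs(ang(vb, vc) - t_ang[0]) > angle_tol or \
                        abs(ang(va, vc) - t_ang[1]) > angle_tol:
                    continue
                err = (np.abs([np.linalg.norm(va), np.linalg.norm(vb),
                               np.linalg.norm(vc)] - targets) / targets
                       ).sum()
                if np.linalg.det(M) < 0:
                    err += 1e-3  # prefer right-handed settings
                if best is None or err < best[0]:
                    best = (err, M)
    if best is None:
        raise ValueError("no basis matching the hinted cell; "
                         "wrong lattice or tolerances too tight")
    M = best[1]
    # new Miller indices are h' = M h, so the basis transforms as
    # A_new = A inv(M)
    A_new = sol.A @ np.linalg.inv(M)
    return IndexingSolution(A_new, _cell_from_A(A_new, sol.voxel_size,
                                                sol.grid_shape),
                            sol.spacegroup, sol.voxel_size, sol.grid_shape)


def refine_cell_symmetry(sol: IndexingSolution, sg: str,
                         spots=None, tolerance: float = 0.05
                         ) -> IndexingSolution:
    """Project the P1 cell onto the constraints of the known space group.

    Orthorhombic: angles to 90; tetragonal: additionally a = b averaged;
    cubic: all lengths averaged; monoclinic (b-unique): alpha = gamma = 90;
    triclinic: unchanged.  The basis A is rotated onto the constrained cell
    by orthogonal Procrustes so assigned Miller indices are preserved.

    Raises ValueError when any parameter must move by more than
    ``tolerance`` (relative), indicating a wrong space group.
    """
    system = space_group(sg).crystal_system
    c = sol.cell
    a, b, cc = c.a, c.b, c.c
    al, be, ga = c.alpha, c.beta, c.gamma
    if system == "triclinic":
        # no constraints to impose; keep the solution as indexed
        return IndexingSolution(sol.A, sol.cell, sg, sol.voxel_size,
                                sol.grid_shape)
    elif system == "monoclinic":
        new = UnitCell(a, b, cc, 90.0, be, 90.0)
    elif system == "orthorhombic":
        new = UnitCell(a, b, cc, 90.0, 90.0, 90.0)
    elif system == "tetragonal":
        ab = 0.5 * (a + b)
        new = UnitCell(ab, ab, cc, 90.0, 90.0, 90.0)
    elif system in ("trigonal", "hexagonal"):
        ab = 0.5 * (a + b)
        new = UnitCell(ab, ab, cc, 90.0, 90.0, 120.0)
    elif system == "cubic":
        abc = (a + b + cc) / 3.0
        new = UnitCell(abc, abc, abc, 90.0, 90.0, 90.0)
    else:
        new = c
    rel_len = np.abs(new.lengths - c.lengths) / c.lengths
    rel_ang = np.abs(new.angles - c.angles) / 90.0
    if np.any(rel_len > tolerance) or np.any(rel_ang > tolerance):
        raise ValueError(
            f"cell {c} violates {system} constraints by more than "
            f"{tolerance:.0%}: wrong space group?")
    # rebuild A: rotate the constrained reciprocal basis onto the current one
    n = np.array(sol.grid_shape, dtype=float) if sol.grid_shape != (0, 0, 0) \
        else np.ones(3)
    scale = (n * sol.voxel_size)[:, None]
    Bstar_new = new.recip_matrix() * scale    # voxel units, unrotated
    # Procrustes: find rotation R minimizing |R Bstar_new - A|
    U, _, Vt = np.linalg.svd(sol.A @ Bstar_new.T)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        U[:, -1] *= -1
        R = U @ Vt
    A_new = R @ Bstar_new
    out = IndexingSolution(A_new, new, sg, sol.voxel_size, sol.grid_shape)
    if spots is not None:
        if len(spots) and isinstance(spots[0], Spot):
            ranked = sorted(spots, key=lambda s: -s.intensity)[:150]
            cents = np.array([s.centroid for s in ranked])
            inten = np.array([s.intensity for s in ranked])
        else:
            cents = np.atleast_2d(spots)
            inten = None
        rel = cents - np.array([nn // 2 for nn in sol.grid_shape])
        A_ref, _ = _refine_assignment(A_new, rel, inten)
        out = IndexingSolution(A_ref, _cell_from_A(
            A_ref, sol.voxel_size, sol.grid_shape), sg, sol.voxel_size,
            sol.grid_shape)
    return out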