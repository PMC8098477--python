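"""Unit cells, space-group operators and phase relations between reflections.

Symmetry data are taken from gemmi.  The phase conventions used throughout:
a symmetry operation (R, t) acts on fractional coordinates as x -> R x + t,
reflections transform as row vectors h' = h R, and structure-factor phases
obey

    phi(h R) = phi(h) - 360 * (h . t)        [degrees]

together with Friedel symmetry phi(-h) = -phi(h) for real densities.
A reflection h is centric when some operation satisfies h R = -h; its phase
is then restricted to 180*(h.t) modulo 180.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import product

import gemmi
import numpy as np


@dataclass(frozen=True)
class UnitCell:
    """Unit-cell lengths (A) and angles (degrees)."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        for name in ("a", "b", "c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"cell length {name} must be positive")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0.0 < ang < 180.0:
                raise ValueError(f"cell angle {name} must lie in (0, 180)")
        # positive-definite metric tensor; gemmi raises for impossible cells
        if self.to_gemmi().volume <= 0:
            raise ValueError("cell metric is not positive-definite")

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c])

    @property
    def angles(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma])

    def to_gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c,
                              self.alpha, self.beta, self.gamma)

    @classmethod
    def from_gemmi(cls, cell: gemmi.UnitCell) -> "UnitCell":
        return cls(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)

    @property
    def volume(self) -> float:
        return self.to_gemmi().volume

    def orth_matrix(self) -> np.ndarray:
        """3x3 matrix taking fractional to Cartesian (A) coordinates."""
        return np.array(self.to_gemmi().orth.mat)

    def frac_matrix(self) -> np.ndarray:
        """3x3 matrix taking Cartesian (A) to fractional coordinates."""
        return np.array(self.to_gemmi().frac.mat)

    def recip_matrix(self) -> np.ndarray:
        """Columns are the reciprocal basis vectors a*, b*, c* in 1/A."""
        return np.linalg.inv(self.orth_matrix()).T

    def d_spacing(self, hkl) -> np.ndarray:
        """Resolution d (A) of reflection(s) hkl; (0,0,0) maps to inf."""
        h = np.atleast_2d(np.asarray(hkl, dtype=float))
        s = h @ self.recip_matrix().T
        q = np.linalg.norm(s, axis=1)
        with np.errstate(divide="ignore"):
            d = np.where(q > 0, 1.0 / np.where(q > 0, q, 1.0), np.inf)
        return d if np.asarray(hkl).ndim > 1 else float(d[0])

    def q_of(self, hkl) -> np.ndarray:
        """Magnitude of the reciprocal-space vector |q| = 1/d in 1/A."""
        h = np.atleast_2d(np.asarray(hkl, dtype=float))
        q = np.linalg.norm(h @ self.recip_matrix().T, axis=1)
        return q if np.asarray(hkl).ndim > 1 else float(q[0])


class SpaceGroupInfo:
    """Space-group operators and the reflection phase relations they imply."""

    def __init__(self, symbol: str):
        sg = gemmi.find_spacegroup_by_name(symbol)
        if sg is None:
            raise ValueError(f"unknown space group {symbol!r}")
        self._gemmi = sg
        self.symbol = sg.hm.replace(" ", "")
        den = gemmi.Op.DEN
        rots, trans = [], []
        for op in sg.operations():
            rots.append(np.array(op.rot, dtype=int) // den)
            trans.append(np.array(op.tran, dtype=float) / den)
        self.rotations = np.array(rots)          # (n_ops, 3, 3), integer
        self.translations = np.array(trans)       # (n_ops, 3), fractional

    @property
    def n_ops(self) -> int:
        return len(self.rotations)

    @property
    def crystal_system(self) -> str:
        return self._gemmi.crystal_system_str()

    @property
    def number(self) -> int:
        return self._gemmi.number

    def __repr__(self):
        return f"SpaceGroupInfo({self.symbol!r})"

    # -- reflection relations -------------------------------------------------

    def equivalents(self, hkl) -> tuple[np.ndarray, np.ndarray]:
        """All h R_s for each input reflection with the phase offsets.

        Returns (heq, dphi) where ``heq[i, s]`` is reflection i transformed by
        operation s and ``dphi[i, s] = -360 (h_i . t_s)`` is the phase change,
        i.e. phi(heq) = phi(h) + dphi.
        """
        h = np.atleast_2d(np.asarray(hkl, dtype=int))
        heq = np.einsum("ij,sjk->isk", h, self.rotations)
        dphi = -360.0 * np.einsum("ij,sj->is", h, self.translations)
        return heq, dphi

    def is_centric(self, hkl) -> np.ndarray:
        """True where some operation maps h to -h."""
        h = np.atleast_2d(np.asarray(hkl, dtype=int))
        heq, _ = self.equivalents(h)
        cen = np.any(np.all(heq == -h[:, None, :], axis=2), axis=1)
        return cen if np.asarray(hkl).ndim > 1 else bool(cen[0])

    def centric_allowed_phase(self, hkl) -> np.ndarray:
        """Allowed phase theta (deg) for centric reflections, modulo 180.

        For a non-centric input the result is NaN.  Derived from phi(hR) =
        phi(h) - 360 h.t with hR = -h and phi(-h) = -phi(h), giving
        phi = 180*(h.t) mod 180.
        """
        h = np.atleast_2d(np.asarray(hkl, dtype=int))
        heq, _ = self.equivalents(h)
        match = np.all(heq == -h[:, None, :], axis=2)
        theta = np.full(len(h), np.nan)
        ht = np.einsum("ij,sj->is", h, self.translations)
        for i in range(len(h)):
            s = np.flatnonzero(match[i])
            if s.size:
                theta[i] = (180.0 * ht[i, s[0]]) % 180.0
        return theta if np.asarray(hkl).ndim > 1 else float(theta[0])

    def is_absent(self, hkl) -> np.ndarray:
        """True where a reflection is systematically absent (screw axes,
        glides)."""
        h = np.atleast_2d(np.asarray(hkl, dtype=int))
        ops = self._gemmi.operations()
        absent = np.array([ops.is_systematically_absent(tuple(int(x)
                                                              for x in row))
                           for row in h])
        return absent if np.asarray(hkl).ndim > 1 else bool(absent[0])

    def permissible_origin_shifts(self) -> tuple[np.ndarray, np.ndarray]:
        """Discrete permissible origin shifts and polar (free) axes.

        A fractional shift o is a permissible origin shift when (R - I) o is a
        lattice vector for every operation, so that shifting the origin by o
        maps one crystallographic origin onto another.  Along polar directions
        (where every rotation fixes the axis) any shift is allowed; those axes
        are reported in the boolean ``free`` vector and the discrete shifts
        have zero component there.

        Returns
        -------
        (shifts, free) : (n, 3) array of fractional shifts, (3,) bool array
        """
        eye = np.eye(3, dtype=int)
        free = np.array([
            all(np.array_equal((R - eye) @ eye[:, ax], [0, 0, 0])
                for R in self.rotations)
            for ax in range(3)
        ])
        # candidate shifts on a 1/12 grid along non-free axes
        base = np.arange(12) / 12.0
        axes = [([0.0] if free[ax] else base) for ax in range(3)]
        shifts = []
        for o in product(*axes):
            o = np.array(o)
            ok = True
            for R in self.rotations:
                v = (R - eye) @ o
                if not np.allclose(v - np.round(v), 0, atol=1e-9):
                    ok = False
                    break
            if ok:
                shifts.append(o)
        return np.array(shifts), free


@lru_cache(maxsize=32)
def space_group(symbol: str) -> SpaceGroupInfo:
    """Cached lookup of :class:`SpaceGroupInfo` by Hermann-Mauguin symbol."""
    return SpaceGroupInfo(symbol)


def unique_reflections(cell: UnitCell, d_min: float) -> np.ndarray:
    """All Friedel-unique reflections with d >= d_min (origin excluded).

    One member of each Friedel pair {h, -h} is kept, chosen so the first
    non-zero index (in l, k, h precedence order used here: h, then k, then l)
    is positive.
    """
    B = cell.recip_matrix()
    # bounding box of the 1/d_min sphere in hkl space
    inv = np.linalg.inv(B)
    hmax = np.ceil(np.linalg.norm(inv, axis=1) / d_min).astype(int)
    rng = [np.arange(-m, m + 1) for m in hmax]
    H = np.array(np.meshgrid(*rng, indexing="ij")).reshape(3, -1).T
    q = np.linalg.norm(H @ B.T, axis=1)
    keep = (q > 0) & (q <= 1.0 / d_min)
    H = H[keep]
    # Friedel-unique: first nonzero of (h, k, l) positive
    first = np.where(H[:, 0] != 0, H[:, 0],
                     np.where(H[:, 1] != 0, H[:, 1], H[:, 2]))
    H = H[first > 0]
    order = np.lexsort((H[:, 2], H[:, 1], H[:, 0]))
    return H[order]
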