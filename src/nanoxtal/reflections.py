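"""Reflection tables: unique Miller indices with intensity, phase and tilt.

The on-disk format is a plain-text table, one reflection per line::

    # nanoxtal reflections
    # cell 16.2 29.1 47.7 90.0 90.0 90.0
    # spacegroup P212121
    # columns h k l intensity phase mult tilt
    1 0 0 12.5 45.0 1 0.0

Phases are degrees in (-180, 180]; tilt is the tilt angle (degrees) of the
central slice that recorded the reflection (NaN when not applicable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .angles import wrap_deg
from .symmetry import UnitCell, space_group


@dataclass
class ReflectionSet:
    """Table of unique reflections with unit cell and space group."""

    hkl: np.ndarray                 # (N, 3) int
    intensity: np.ndarray           # (N,) float, >= 0
    phase: np.ndarray               # (N,) float degrees in (-180, 180]
    cell: UnitCell
    spacegroup: str = "P1"
    multiplicity: np.ndarray | None = None
    tilt: np.ndarray | None = None  # recording tilt angle per reflection

    def __post_init__(self):
        self.hkl = np.atleast_2d(np.asarray(self.hkl, dtype=int))
        n = len(self.hkl)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.phase = np.asarray(wrap_deg(self.phase), dtype=float).reshape(n)
        if self.multiplicity is None:
            self.multiplicity = np.ones(n, dtype=int)
        else:
            self.multiplicity = np.asarray(self.multiplicity, dtype=int)
        if self.tilt is None:
            self.tilt = np.full(n, np.nan)
        else:
            self.tilt = np.asarray(self.tilt, dtype=float)
        if not (len(self.intensity) == len(self.phase)
                == len(self.multiplicity) == len(self.tilt) == n):
            raise ValueError("column lengths disagree")
        if n and len(np.unique(self.hkl, axis=0)) != n:
            raise ValueError("duplicate Miller indices in reflection set")

    def __len__(self):
        return len(self.hkl)

    @property
    def sg(self):
        return space_group(self.spacegroup)

    def q(self) -> np.ndarray:
        """|q| = 1/d in 1/A for every reflection."""
        return np.atleast_1d(self.cell.q_of(self.hkl))

    def d(self) -> np.ndarray:
        return 1.0 / self.q()

    def copy(self) -> "ReflectionSet":
        return ReflectionSet(self.hkl.copy(), self.intensity.copy(),
                             self.phase.copy(), self.cell, self.spacegroup,
                             self.multiplicity.copy(), self.tilt.copy())

    def select(self, mask) -> "ReflectionSet":
        return ReflectionSet(self.hkl[mask], self.intensity[mask],
                             self.phase[mask], self.cell, self.spacegroup,
                             self.multiplicity[mask], self.tilt[mask])

    def index_map(self) -> dict:
        """Map (h, k, l) tuple -> row index."""
        return {tuple(h): i for i, h in enumerate(self.hkl)}

    def common(self, other: "ReflectionSet") -> tuple[np.ndarray, np.ndarray]:
        """Row indices (into self, other) of the shared reflections."""
        amap = self.index_map()
        ia, ib = [], []
        for j, h in enumerate(other.hkl):
            i = amap.get(tuple(h))
            if i is not None:
                ia.append(i)
                ib.append(j)
        return np.array(ia, dtype=int), np.array(ib, dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "h": self.hkl[:, 0], "k": self.hkl[:, 1], "l": self.hkl[:, 2],
            "intensity": self.intensity, "phase": self.phase,
            "mult": self.multiplicity, "tilt": self.tilt,
        })

    # -- text serialization ---------------------------------------------------

    def write(self, path) -> None:
        with open(path, "w") as fh:
            c = self.cell
            fh.write("# nanoxtal reflections\n")
            fh.write(f"# cell {c.a:.6g} {c.b:.6g} {c.c:.6g} "
                     f"{c.alpha:.6g} {c.beta:.6g} {c.gamma:.6g}\n")
            fh.write(f"# spacegroup {self.spacegroup}\n")
            fh.write("# columns h k l intensity phase mult tilt\n")
            for i in range(len(self)):
                h, k, l = self.hkl[i]
                fh.write(f"{h} {k} {l} {self.intensity[i]:.10g} "
                         f"{self.phase[i]:.10g} {self.multiplicity[i]} "
                         f"{self.tilt[i]:.10g}\n")

    @classmethod
    def read(cls, path) -> "ReflectionSet":
        cell = None
        sg = "P1"
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    parts = line[1:].split()
                    if parts and parts[0] == "cell":
                        vals = [float(x) for x in parts[1:7]]
                        cell = UnitCell(*vals)
                    elif parts and parts[0] == "spacegroup":
                        sg = parts[1]
                    continue
                parts = line.split()
                if len(parts) != 7:
                    raise ValueError(
                        f"{path}: malformed row at line {lineno}: {line!r}")
                try:
                    rows.append([float(x) for x in parts])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: malformed row at line {lineno}") from exc
        if cell is None:
            raise ValueError(f"{path}: missing '# cell' header")
        if not rows:
            return cls(np.zeros((0, 3), dtype=int), np.zeros(0), np.zeros(0),
                       cell, sg, np.zeros(0, dtype=int), np.zeros(0))
        arr = np.array(rows)
        return cls(arr[:, :3].astype(int), arr[:, 3], arr[:, 4], cell, sg,
                   arr[:, 5].astype(int), arr[:, 6])
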