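"""Fast evaluation of resultant scores on fractional-cell search grids.

The origin searches need sums of the form

    S(u) = Re sum_h c_h exp(-2 pi i h . u)

at every node u = (j1/n1, j2/n2, j3/n3) of the search grid.  This is a 3D
DFT, but the coefficients occupy only a small box of Miller indices, so
evaluating it as three successive per-axis matrix contractions ("zoom DFT")
is much faster than a full-grid FFT, especially for the prime-sized grids a
0.2 A sampling interval tends to produce.
"""

from __future__ import annotations

import numpy as np


def grid_resultant_score(hkl, coeffs, dims) -> np.ndarray:
    """Re sum_h c_h e^{-2 pi i h.u} on the full (n1, n2, n3) search grid.

    ``hkl`` is (N, 3) integer, ``coeffs`` complex (N,).  Duplicate indices
    accumulate.  Single precision is used internally; the score only ranks
    candidates, exact metrics are recomputed on the shortlist downstream.
    """
    hkl = np.asarray(hkl, dtype=int)
    coeffs = np.asarray(coeffs, dtype=complex)
    lo = hkl.min(axis=0)
    hi = hkl.max(axis=0)
    box = tuple(hi - lo + 1)
    c = np.zeros(box, dtype=np.complex64)
    off = hkl - lo
    np.add.at(c, (off[:, 0], off[:, 1], off[:, 2]),
              coeffs.astype(np.complex64))
    out = c
    for ax, n in enumerate(dims):
        idx = lo[ax] + np.arange(box[ax])
        M = np.exp(-2j * np.pi * np.outer(np.arange(n) / n,
                                          idx)).astype(np.complex64)
        out = np.moveaxis(np.tensordot(M, out, axes=(1, ax)), 0, ax)
    return np.ascontiguousarray(out.real)
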