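"""Circular (phase) arithmetic in degrees.

All phases in this package are degrees on the interval (-180, 180].
"""

from __future__ import annotations

import numpy as np


def wrap_deg(angle):
    """Wrap angle(s) in degrees to the interval (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    wrapped = -((-a + 180.0) % 360.0 - 180.0)
    return wrapped if wrapped.ndim else float(wrapped)


def weighted_phase_stats(phases_deg, weights):
    """Intensity-weighted circular mean and spread of phases.

    The mean is ``arg(sum w_i exp(i phi_i))``.  The spread is the square root
    of the weighted mean squared *wrapped* deviation about that mean, which
    for tightly clustered phases agrees with the linear standard deviation.

    Parameters
    ----------
    phases_deg : array-like
        Phases in degrees.
    weights : array-like
        Non-negative weights; must not all be zero.

    Returns
    -------
    (mean_deg, std_deg) : tuple of float
    """
    phi = np.asarray(phases_deg, dtype=float)
    w = np.asarray(weights, dtype=float)
    if phi.size == 0:
        raise ValueError("no phases given")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("weights sum to zero")
    z = np.sum(w * np.exp(1j * np.deg2rad(phi)))
    mean = np.rad2deg(np.angle(z))
    dev = wrap_deg(phi - mean)
    std = float(np.sqrt(np.sum(w * dev**2) / wsum))
    return float(wrap_deg(mean)), std


def weighted_circular_mean(phases_deg, weights):
    """Intensity-weighted circular mean phase in degrees."""
    return weighted_phase_stats(phases_deg, weights)[0]
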