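"""Shared factory for synthetic Fourier volumes with injected peaks."""

import numpy as np

from nanoxtal.volume import FourierVolume


def make_peak_volume(shape=(48, 48, 48), peak_center=(24, 24, 24),
                     volume=500.0, phase=40.0, sigma=0.5, background=2.0,
                     bg_slope=0.0, noise=0.0, seed=0, outlier=None):
    """Complex volume with one injected compact peak of known integrated
    intensity and uniform phase on a (possibly sloped, noisy) background.

    The peak is a Gaussian truncated to the center voxel and its 6 face
    neighbors, normalized so its discrete mass is exactly ``volume`` --
    the shape of a well-sampled Bragg peak after tapering, and an exact
    oracle for the threshold-based extraction sum.
    """
    rng = np.random.default_rng(seed)
    idx = np.indices(shape).astype(float)
    amp2 = np.full(shape, background, dtype=float)
    if bg_slope:
        amp2 += bg_slope * (idx[2] - shape[2] / 2)
    amp2 = np.clip(amp2, 0.01, None)
    if noise:
        amp2 += noise * rng.random(shape)
    d2 = sum((idx[a] - peak_center[a])**2 for a in range(3))
    kernel = np.exp(-d2 / (2 * sigma**2))
    kernel[d2 > 1.5] = 0.0          # truncate to center + faces
    peak_i = volume * kernel / kernel.sum()
    phases = np.deg2rad(np.full(shape, 0.0))
    phases[peak_i > 0] = np.deg2rad(phase)
    if outlier is not None:
        pos, odeg = outlier
        phases[pos] = np.deg2rad(odeg)
    F = np.sqrt(amp2 + peak_i) * np.exp(1j * phases)
    return FourierVolume(F, 1.0)
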