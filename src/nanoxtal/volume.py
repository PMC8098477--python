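"""Real-space density volumes and their discrete Fourier transforms.

A :class:`Volume` is a real 3D scalar field on a regular grid with a voxel
size in Angstrom; voxel (0, 0, 0) sits at the grid corner.  The Fourier-space
counterpart :class:`FourierVolume` keeps the complex transform with the zero
frequency at the central voxel ``N // 2`` along each axis, so that reciprocal
voxel coordinates are measured relative to the grid center and one reciprocal
voxel spans ``1 / (N * voxel)`` 1/A.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft


@dataclass
class Volume:
    """Real-valued density grid with voxel size in Angstrom."""

    grid: np.ndarray
    voxel_size: float

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 3:
            raise ValueError("volume grid must be 3D")
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be positive")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self):
        return self.grid.shape

    def copy(self) -> "Volume":
        return Volume(self.grid.copy(), self.voxel_size)


@dataclass
class FourierVolume:
    """Complex 3D transform with the phase origin at the central voxel."""

    grid: np.ndarray          # complex, zero frequency at N//2 per axis
    voxel_size: float         # real-space voxel size in A

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=complex)
        if self.grid.ndim != 3:
            raise ValueError("Fourier grid must be 3D")

    @property
    def shape(self):
        return self.grid.shape

    @property
    def center(self) -> np.ndarray:
        """Index of the zero-frequency voxel."""
        return np.array([n // 2 for n in self.grid.shape])

    @property
    def recip_voxel_size(self) -> np.ndarray:
        """Reciprocal voxel size (1/A) along each axis."""
        return np.array([1.0 / (n * self.voxel_size) for n in self.grid.shape])

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.grid) ** 2

    @property
    def phase(self) -> np.ndarray:
        """Phase in degrees on (-180, 180]."""
        ph = np.rad2deg(np.angle(self.grid))
        # map -180 exactly to +180 for convention consistency
        ph[ph == -180.0] = 180.0
        return ph

    def q_grid(self) -> np.ndarray:
        """|q| (1/A) at every reciprocal voxel."""
        axes = [
            (np.arange(n) - n // 2) / (n * self.voxel_size)
            for n in self.grid.shape
        ]
        qx, qy, qz = np.meshgrid(*axes, indexing="ij")
        return np.sqrt(qx**2 + qy**2 + qz**2)


def fourier_transform(vol: Volume, origin: str = "center") -> FourierVolume:
    """Discrete Fourier transform of a volume.

    With ``origin='center'`` the real-space phase origin is taken at voxel
    ``N // 2`` along each axis (the volume is cyclically rolled so that
    voxel reaches index 0 before the FFT), so a density centered there
    produces slowly varying, non-split phases around its Bragg peaks.
    ``origin='corner'`` is the plain FFT convention: a density sitting
    mid-window then carries an alternating (-1)^k phase factor -- the
    phase-splitting regime that preprocessing exists to remove.  The output
    zero frequency always sits at ``N // 2``.
    """
    if origin == "center":
        shifts = [-(n // 2) for n in vol.grid.shape]
        g = np.roll(vol.grid, shifts, axis=(0, 1, 2))
    elif origin == "corner":
        g = vol.grid
    else:
        raise ValueError(f"unknown origin convention {origin!r}")
    F = scipy.fft.fftshift(scipy.fft.fftn(g))
    return FourierVolume(F, vol.voxel_size)


def inverse_fourier_transform(fv: FourierVolume) -> Volume:
    """Inverse of :func:`fourier_transform` (real part of the synthesis)."""
    F = scipy.fft.ifftshift(fv.grid)
    vol = scipy.fft.ifftn(F).real
    shifts = [n // 2 for n in vol.shape]
    return Volume(np.roll(vol, shifts, axis=(0, 1, 2)), fv.voxel_size)
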