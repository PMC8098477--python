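"""Synthetic nanocrystals, tilt series, tomograms and real-space damage.

Crystals are built from pseudo-structures: Gaussian scatterers placed at
random in the asymmetric unit and expanded by the space-group operators.
The crystal density (a finite block of N x N x N unit cells) is band-limited
at the working resolution, embedded centered in a padded cube, rotated to a
random orientation, projected into a dose-symmetric tilt series and
reconstructed by weighted back-projection.  Radiation damage is modeled in
real space as local blurring events ("hits") accumulated across the tilt
series.

Real-space gridding assumes orthogonal cells (alpha = beta = gamma = 90);
reciprocal-space simulations elsewhere in the package have no such
restriction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft
import scipy.ndimage
from scipy.spatial.transform import Rotation

from .symmetry import UnitCell, space_group, unique_reflections
from .reflections import ReflectionSet
from .volume import Volume


# ---------------------------------------------------------------------------
# pseudo-structures and structure factors
# ---------------------------------------------------------------------------

@dataclass
class PseudoStructure:
    """Gaussian-scatterer model: fractional positions, widths and weights."""

    frac: np.ndarray        # (n, 3) fractional coordinates in [0, 1)
    sigma: np.ndarray       # (n,) real-space Gaussian width in A
    weight: np.ndarray      # (n,) scattering weight (arbitrary units)
    cell: UnitCell
    spacegroup: str = "P1"

    def __len__(self):
        return len(self.frac)


def generate_pseudo_structure(seed, n_atoms: int, cell: UnitCell,
                              sg: str = "P1",
                              sigma_range=(0.7, 1.2),
                              weight_range=(6.0, 16.0)) -> PseudoStructure:
    """Random Gaussian-blob structure obeying the space-group symmetry.

    ``n_atoms`` scatterers are placed uniformly in the cell (serving as the
    asymmetric-unit content) and expanded by all symmetry operations, so the
    output has ``n_atoms * n_ops`` atoms and its structure factors satisfy
    |F(hR)| = |F(h)| exactly.  Positions are wrapped into [0, 1).
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    rng = np.random.default_rng(seed)
    info = space_group(sg)
    asu = rng.random((n_atoms, 3))
    sig = rng.uniform(*sigma_range, size=n_atoms)
    wt = rng.uniform(*weight_range, size=n_atoms)
    pos, sigmas, weights = [], [], []
    for R, t in zip(info.rotations, info.translations):
        pos.append((asu @ R.T + t) % 1.0)
        sigmas.append(sig)
        weights.append(wt)
    return PseudoStructure(np.concatenate(pos), np.concatenate(sigmas),
                           np.concatenate(weights), cell, info.symbol)


def structure_factors(model: PseudoStructure, d_min: float) -> ReflectionSet:
    """Direct-summation structure factors of a pseudo-structure.

    F(h) = sum_j w_j exp(-2 pi^2 sigma_j^2 q^2) exp(2 pi i h.x_j), evaluated
    for every Friedel-unique reflection with d >= d_min.  Systematically
    absent reflections (exactly zero by symmetry, with ill-defined phases)
    are excluded.  The returned set carries intensity |F|^2 and phase
    arg(F) on the crystallographic origin implied by the atomic
    coordinates.
    """
    info = space_group(model.spacegroup)
    H = unique_reflections(model.cell, d_min)
    H = H[~info.is_absent(H)]
    q = np.atleast_1d(model.cell.q_of(H))
    form = model.weight[None, :] * np.exp(
        -2.0 * np.pi**2 * model.sigma[None, :]**2 * q[:, None]**2)
    phase = 2.0 * np.pi * (H @ model.frac.T)
    F = np.sum(form * np.exp(1j * phase), axis=1)
    return ReflectionSet(H, np.abs(F)**2, np.rad2deg(np.angle(F)),
                         model.cell, model.spacegroup)


def unit_cell_density(model: PseudoStructure, shape) -> np.ndarray:
    """Periodic density of one unit cell sampled on ``shape`` grid points.

    Orthogonal cells only.  Used as a reference map and as the tile for
    finite-crystal construction.
    """
    _require_orthogonal(model.cell)
    lengths = model.cell.lengths
    grid = np.zeros(shape)
    axes = [np.arange(n) * (L / n) for n, L in zip(shape, lengths)]
    for x, s, w in zip(model.frac, model.sigma, model.weight):
        center = x * lengths
        # minimal-image distance along each axis keeps the density periodic
        d2 = 0.0
        for ax in range(3):
            d = np.abs(axes[ax] - center[ax])
            d = np.minimum(d, lengths[ax] - d)
            sh = [1, 1, 1]
            sh[ax] = -1
            d2 = d2 + d.reshape(sh) ** 2
        # normalized Gaussian: `weight` is the integrated scattering power,
        # consistent with F(h) = w exp(-2 pi^2 sigma^2 q^2) e^{2 pi i h.x}
        grid += (w / ((2 * np.pi) ** 1.5 * s**3)) \
            * np.exp(-d2 / (2.0 * s**2))
    return grid


def _require_orthogonal(cell: UnitCell):
    if not np.allclose(cell.angles, 90.0, atol=1e-6):
        raise ValueError("real-space simulation requires an orthogonal cell")


# ---------------------------------------------------------------------------
# crystal density
# ---------------------------------------------------------------------------

def build_crystal_density(model: PseudoStructure, n_cells=(3, 3, 3),
                          d_min: float = 3.0, voxel: float = 1.0,
                          pad_factor: float = 1.4) -> Volume:
    """Finite nanocrystal density: tiled unit cells, band-limited, padded.

    The model density is tiled ``n_cells`` times per axis, low-pass filtered
    at ``d_min`` and embedded centered in a cubic zero-padded grid whose edge
    is at least ``pad_factor`` times the crystal diagonal, so any rotation
    keeps the density inside the volume.

    Raises
    ------
    ValueError
        "undersampled" when ``voxel > d_min / 2`` (Nyquist violation).
    """
    if voxel > d_min / 2.0 + 1e-12:
        raise ValueError(f"undersampled: voxel {voxel} A exceeds d_min/2 "
                         f"= {d_min / 2.0} A")
    n_cells = np.asarray(n_cells, dtype=int)
    if np.any(n_cells < 1):
        raise ValueError("n_cells must be >= 1 along each axis")
    _require_orthogonal(model.cell)
    lengths = model.cell.lengths
    extent = lengths * n_cells              # crystal block size in A
    diag = np.linalg.norm(extent)
    edge = int(np.ceil(pad_factor * diag / voxel))
    grid = np.zeros((edge, edge, edge))
    # atoms at absolute positions: the cell dimensions are generally not an
    # integer number of voxels, so the sampled crystal is imperfectly
    # periodic on the grid -- the regime the preprocessing stage must handle
    start = (edge * voxel - extent) / 2.0
    offsets = np.array(np.meshgrid(*[np.arange(n) for n in n_cells],
                                   indexing="ij")).reshape(3, -1).T
    reach = 4.0
    for x, s, w in zip(model.frac, model.sigma, model.weight):
        for off in offsets:
            center = start + (off + x) * lengths
            cvox = center / voxel
            lo = np.maximum(np.floor(cvox - reach * s / voxel).astype(int), 0)
            hi = np.minimum(np.ceil(cvox + reach * s / voxel).astype(int) + 1,
                            edge)
            if np.any(lo >= hi):
                continue
            ax = [(np.arange(lo[d], hi[d]) * voxel - center[d]) ** 2
                  for d in range(3)]
            d2 = (ax[0][:, None, None] + ax[1][None, :, None]
                  + ax[2][None, None, :])
            grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += \
                (w / ((2 * np.pi) ** 1.5 * s**3)) \
                * np.exp(-d2 / (2.0 * s**2))
    grid = _lowpass(grid, voxel, d_min)
    return Volume(grid, voxel)


def _lowpass(grid: np.ndarray, voxel: float, d_min: float) -> np.ndarray:
    """Spherical low-pass at 1/d_min with a soft (half-cosine) edge."""
    freqs = [scipy.fft.fftfreq(n, d=voxel) for n in grid.shape]
    qx, qy, qz = np.meshgrid(*freqs, indexing="ij")
    q = np.sqrt(qx**2 + qy**2 + qz**2)
    qc = 1.0 / d_min
    width = 0.05 * qc
    mask = 0.5 * (1.0 + np.cos(np.pi * np.clip((q - qc) / width, 0, 1)))
    mask[q <= qc] = 1.0
    return scipy.fft.ifftn(scipy.fft.fftn(grid) * mask).real


# ---------------------------------------------------------------------------
# orientations and tilt series
# ---------------------------------------------------------------------------

def random_rotation(seed) -> np.ndarray:
    """Uniform random rotation matrix (Haar measure on SO(3))."""
    rng = np.random.default_rng(seed)
    return Rotation.random(random_state=rng).as_matrix()


def rotate_volume(vol: Volume, R: np.ndarray) -> Volume:
    """Rotate a volume about its grid center (trilinear interpolation)."""
    center = (np.array(vol.shape) - 1) / 2.0
    offset = center - np.asarray(R).T @ center
    rotated = scipy.ndimage.affine_transform(
        vol.grid, np.asarray(R).T, offset=offset, order=1, mode="constant")
    return Volume(rotated, vol.voxel_size)


def tilt_scheme_angles(tilt_range: float, increment: float) -> np.ndarray:
    """Sorted tilt angles for a +/- ``tilt_range`` scheme."""
    if increment <= 0 or tilt_range <= 0:
        raise ValueError("empty tilt scheme")
    n = int(round(tilt_range / increment))
    if abs(n * increment - tilt_range) > 1e-9:
        raise ValueError("increment must divide the tilt range")
    return np.arange(-n, n + 1) * increment


def dose_symmetric_order(angles: np.ndarray) -> np.ndarray:
    """Acquisition index n = 1, 2, ... for each (sorted) tilt angle.

    The scheme records 0 first, then alternates negative/positive:
    0, -d, +d, -2d, +2d, ...
    """
    angles = np.asarray(angles, dtype=float)
    ranked = sorted(range(len(angles)),
                    key=lambda i: (abs(angles[i]), angles[i] > 0))
    n = np.empty(len(angles), dtype=int)
    for rank, i in enumerate(ranked):
        n[i] = rank + 1
    return n


@dataclass
class TiltSeries:
    """Stack of projections in ascending-angle order with acquisition index."""

    images: np.ndarray            # (n_tilts, nx, ny)
    tilt_angles: np.ndarray       # degrees, ascending
    acquisition_index: np.ndarray  # dose-symmetric n per image
    voxel_size: float

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=float)
        self.tilt_angles = np.asarray(self.tilt_angles, dtype=float)
        self.acquisition_index = np.asarray(self.acquisition_index, dtype=int)
        if len(np.unique(self.tilt_angles)) != len(self.tilt_angles):
            raise ValueError("tilt angles must be unique")

    def __len__(self):
        return len(self.images)


def _project_at_angle(grid: np.ndarray, angle_deg: float) -> np.ndarray:
    """Line integral along the beam axis of the volume tilted about x.

    The detector axis y' points along (cos a, sin a) in the (y, z) plane of
    the specimen, so the 2D transform of the projection equals the central
    slice of the 3D transform along that direction (Fourier slice theorem);
    the back-projector uses the matching geometry.  Trilinear interpolation.
    """
    if angle_deg == 0.0:
        return grid.sum(axis=2)
    a = np.deg2rad(angle_deg)
    M = np.array([[1, 0, 0],
                  [0, np.cos(a), -np.sin(a)],
                  [0, np.sin(a), np.cos(a)]])
    center = (np.array(grid.shape) - 1) / 2.0
    offset = center - M @ center
    rot = scipy.ndimage.affine_transform(grid, M, offset=offset, order=1,
                                         mode="constant")
    return rot.sum(axis=2)


def project_tilt_series(vol: Volume, tilt_range: float = 60.0,
                        increment: float = 3.0) -> TiltSeries:
    """Project a volume into a dose-symmetric tilt series.

    Each image is the line integral of the volume rotated about the x axis
    by the tilt angle; +/-60 deg at 3 deg steps yields 41 images.
    """
    angles = tilt_scheme_angles(tilt_range, increment)
    images = np.stack([_project_at_angle(vol.grid, a) for a in angles])
    return TiltSeries(images, angles, dose_symmetric_order(angles),
                      vol.voxel_size)


# ---------------------------------------------------------------------------
# weighted back-projection
# ---------------------------------------------------------------------------

def reconstruct_tomogram(ts: TiltSeries, depth: int | None = None) -> Volume:
    """Weighted back-projection reconstruction of a tilt series.

    Each projection is ramp-filtered (r-weighting) along the axis
    perpendicular to the tilt axis and smeared back along its beam
    direction.  The output Fourier transform is populated only on the
    sampled central slices, leaving the missing wedge empty.
    """
    if len(ts) < 3:
        raise ValueError("need at least 3 images to reconstruct")
    shapes = {im.shape for im in ts.images}
    if len(shapes) != 1:
        raise ValueError("inconsistent image shapes in tilt series")
    nx, ny = ts.images[0].shape
    nz = depth or ny
    out = np.zeros((nx, ny, nz))
    cy = ny // 2
    cz = nz // 2
    yy, zz = np.meshgrid(np.arange(ny) - cy, np.arange(nz) - cz,
                         indexing="ij")
    for img, angle in zip(ts.images, ts.tilt_angles):
        filt = _ramp_filter(img)
        a = np.deg2rad(angle)
        # coordinate of each voxel along the tilted detector axis
        ypos = yy * np.cos(a) + zz * np.sin(a) + cy
        i0 = np.floor(ypos).astype(int)
        frac = ypos - i0
        i1 = i0 + 1
        valid = (i0 >= 0) & (i1 < ny)
        i0c = np.clip(i0, 0, ny - 1)
        i1c = np.clip(i1, 0, ny - 1)
        contrib = (filt[:, i0c.ravel()] * (1.0 - frac.ravel())
                   + filt[:, i1c.ravel()] * frac.ravel())
        contrib *= valid.ravel()
        out += contrib.reshape(nx, ny, nz)
    out *= np.pi / (2.0 * len(ts))
    return Volume(out, ts.voxel_size)


def _ramp_filter(img: np.ndarray) -> np.ndarray:
    """R-weighted ramp filter applied along the second image axis."""
    ny = img.shape[1]
    f = scipy.fft.fftfreq(ny)
    ramp = np.abs(f)
    ramp[0] = 0.25 / ny  # small DC retention avoids a hollow reconstruction
    return scipy.fft.ifft(scipy.fft.fft(img, axis=1) * ramp[None, :],
                          axis=1).real


# ---------------------------------------------------------------------------
# real-space radiation damage
# ---------------------------------------------------------------------------

@dataclass
class DamageHitModel:
    """Local-blurring damage model: hit count, box edge and kernel width."""

    n_hits: int
    box_edge: float = 5.0       # A
    kernel_sigma: float = 1.0   # A
    seed: int | None = None

    def __post_init__(self):
        if self.n_hits < 0:
            raise ValueError("n_hits must be >= 0")
        if self.box_edge <= 0 or self.kernel_sigma <= 0:
            raise ValueError("box edge and kernel sigma must be positive")


def _crystal_bbox(grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Bounding box (lo, hi inclusive) of the non-negligible density."""
    # band-limiting leaves low-amplitude ripples across the padded volume;
    # a few-percent threshold recovers the actual crystal support
    mask = np.abs(grid) > 0.02 * np.max(np.abs(grid))
    if not mask.any():
        raise ValueError("empty volume")
    idx = np.where(mask)
    lo = np.array([ax.min() for ax in idx])
    hi = np.array([ax.max() for ax in idx])
    return lo, hi


def apply_damage_hits(vol: Volume, model: DamageHitModel,
                      rng=None) -> Volume:
    """Blur ``n_hits`` random cubic subvolumes of the crystal in place-copy.

    Each hit replaces a cube of edge ``box_edge`` (A), centered at a site
    drawn uniformly over the crystal bounding box, with its Gaussian-filtered
    copy (sigma ``kernel_sigma`` A per axis).  Boxes crossing the volume edge
    are clipped to the valid region.  Deterministic for a fixed seed.
    """
    out = vol.copy()
    if model.n_hits == 0:
        return out
    if rng is None:
        rng = np.random.default_rng(model.seed)
    lo, hi = _crystal_bbox(vol.grid)
    half = max(1, int(round(model.box_edge / vol.voxel_size / 2.0)))
    sigma_vox = model.kernel_sigma / vol.voxel_size
    shape = np.array(vol.shape)
    sites = rng.integers(lo, hi + 1, size=(model.n_hits, 3))
    for site in sites:
        a = np.maximum(site - half, 0)
        b = np.minimum(site + half + 1, shape)
        sub = out.grid[a[0]:b[0], a[1]:b[1], a[2]:b[2]]
        out.grid[a[0]:b[0], a[1]:b[1], a[2]:b[2]] = \
            scipy.ndimage.gaussian_filter(sub, sigma_vox, mode="nearest")
    return out


def damaged_tilt_series(vol: Volume, hits_per_image: int,
                        tilt_range: float = 60.0, increment: float = 3.0,
                        box_edge: float = 5.0, kernel_sigma: float = 1.0,
                        seed=None) -> TiltSeries:
    """Tilt series with linearly accumulating damage.

    Following the dose-symmetric acquisition order, ``hits_per_image`` blur
    events are applied to the evolving crystal volume before each projection,
    so the image acquired n-th carries ``n * hits_per_image`` cumulative hits.
    """
    angles = tilt_scheme_angles(tilt_range, increment)
    order = dose_symmetric_order(angles)
    rng = np.random.default_rng(seed)
    model = DamageHitModel(hits_per_image, box_edge, kernel_sigma)
    current = vol
    images = np.empty((len(angles),) + vol.shape[:1]
                      + (vol.shape[1],))
    # acquire in dose order, store in angle order
    for n in range(1, len(angles) + 1):
        idx = int(np.flatnonzero(order == n)[0])
        if hits_per_image > 0:
            current = apply_damage_hits(current, model, rng=rng)
        images[idx] = _project_at_angle(current.grid, angles[idx])
    return TiltSeries(images, angles, order, vol.voxel_size)
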