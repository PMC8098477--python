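import numpy as np
import pytest
import scipy.fft
import scipy.stats

from nanoxtal.symmetry import UnitCell, space_group
from nanoxtal.sim_crystal import (DamageHitModel, apply_damage_hits,
                                  build_crystal_density,
                                  damaged_tilt_series, dose_symmetric_order,
                                  generate_pseudo_structure,
                                  project_tilt_series, random_rotation,
                                  reconstruct_tomogram, rotate_volume,
                                  structure_factors, tilt_scheme_angles,
                                  unit_cell_density)
from nanoxtal.volume import Volume, fourier_transform


class TestPseudoStructure:
    def test_p1_single_atom(self):
        cell = UnitCell(10, 10, 10)
        m = generate_pseudo_structure(1, 1, cell, "P1")
        assert len(m) == 1

    def test_symmetry_expansion_count(self):
        cell = UnitCell(16.2, 29.1, 47.7)
        m = generate_pseudo_structure(1, 5, cell, "P212121")
        assert len(m) == 20  # 4 ops x 5 atoms

    def test_deterministic(self):
        cell = UnitCell(10, 12, 14)
        a = generate_pseudo_structure(5, 3, cell, "P212121")
        b = generate_pseudo_structure(5, 3, cell, "P212121")
        assert np.array_equal(a.frac, b.frac)
        assert np.array_equal(a.sigma, b.sigma)

    def test_structure_factor_symmetry(self):
        """|F(hR)| = |F(h)| for every operation (direct-sum oracle)."""
        cell = UnitCell(16.2, 29.1, 47.7)
        m = generate_pseudo_structure(2, 4, cell, "P212121")
        rs = structure_factors(m, 4.0)
        sg = space_group("P212121")
        idx = rs.index_map()
        checked = 0
        heq, _ = sg.equivalents(rs.hkl)
        for i in range(len(rs)):
            for s in range(1, sg.n_ops):
                g = tuple(heq[i, s])
                j = idx.get(g, idx.get(tuple(-np.array(g))))
                if j is None:
                    continue
                assert rs.intensity[j] == pytest.approx(rs.intensity[i],
                                                        rel=1e-6)
                checked += 1
        assert checked > 100

    def test_structure_factors_match_fft_of_density(self):
        """Dual route: direct summation vs FFT of the periodic cell map."""
        cell = UnitCell(12.0, 14.0, 16.0)
        m = generate_pseudo_structure(4, 3, cell, "P1")
        rs = structure_factors(m, 4.0)
        shape = (36, 42, 48)
        rho = unit_cell_density(m, shape)
        F = scipy.fft.fftn(rho)  # plain DFT sum over the periodic cell
        idx = rs.index_map()
        # compare amplitude RATIOS and phases, which are scale-free
        hs = [(1, 0, 0), (0, 2, 1), (1, 1, 2), (1, -2, 2), (0, 0, 3)]
        amps_fft, amps_dir, ph_fft, ph_dir = [], [], [], []
        for h in hs:
            Fh = F[h[0] % shape[0], h[1] % shape[1], h[2] % shape[2]]
            amps_fft.append(abs(Fh))
            ph_fft.append(np.angle(Fh))
            i = idx[h]
            amps_dir.append(np.sqrt(rs.intensity[i]))
            ph_dir.append(np.deg2rad(rs.phase[i]))
        amps_fft = np.array(amps_fft) / amps_fft[0]
        amps_dir = np.array(amps_dir) / amps_dir[0]
        assert np.allclose(amps_fft, amps_dir, rtol=2e-2)
        # FFT convention: F[k] = sum rho(x) e^{-2pi i kx/N} -> conjugate
        # of the crystallographic e^{+2pi i h.x}; compare accordingly
        for pf, pd in zip(ph_fft, ph_dir):
            assert np.cos(pf + pd) == pytest.approx(1.0, abs=1e-3)


class TestCrystalDensity:
    def test_nyquist_guard(self, p1_model):
        with pytest.raises(ValueError, match="undersampled"):
            build_crystal_density(p1_model, (2, 2, 2), d_min=3.0, voxel=2.0)

    def test_point_scatterer_lattice(self):
        """A single narrow scatterer tiled 2x2x2 gives 8 maxima on the
        lattice nodes."""
        cell = UnitCell(8, 8, 8)
        from nanoxtal.sim_crystal import PseudoStructure
        m = PseudoStructure(np.array([[0.5, 0.5, 0.5]]), np.array([0.6]),
                            np.array([10.0]), cell, "P1")
        vol = build_crystal_density(m, (2, 2, 2), d_min=2.5, voxel=1.0)
        g = vol.grid
        thresh = 0.5 * g.max()
        import scipy.ndimage
        labels, n = scipy.ndimage.label(g > thresh)
        assert n == 8
        coms = np.array(scipy.ndimage.center_of_mass(
            g, labels, np.arange(1, 9)))
        # pairwise displacements are multiples of the 8 A lattice constant
        d = coms[:, None, :] - coms[None, :, :]
        frac = d / 8.0
        assert np.allclose(frac, np.round(frac), atol=0.06)

    def test_density_scales_with_crystal_size(self, p1_model):
        v2 = build_crystal_density(p1_model, (2, 2, 2), 3.0, 1.0)
        v3 = build_crystal_density(p1_model, (3, 3, 3), 3.0, 1.0)
        ratio = v3.grid.sum() / v2.grid.sum()
        assert ratio == pytest.approx((3 / 2)**3, rel=0.02)


class TestRotations:
    def test_orthonormal_and_deterministic(self):
        R = random_rotation(11)
        assert np.allclose(R.T @ R, np.eye(3), atol=1e-10)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)
        assert np.array_equal(R, random_rotation(11))

    def test_haar_angle_distribution(self):
        """Rotation angles over many draws follow the SO(3) Haar density
        proportional to sin^2(theta/2) (chi-squared test)."""
        rng = np.random.default_rng(0)
        angles = []
        for _ in range(10000):
            R = random_rotation(rng)
            angles.append(np.arccos(np.clip((np.trace(R) - 1) / 2, -1, 1)))
        angles = np.array(angles)
        edges = np.linspace(0, np.pi, 21)
        obs, _ = np.histogram(angles, bins=edges)
        theta = np.linspace(0, np.pi, 2001)
        dens = np.sin(theta / 2)**2
        cdf = np.cumsum(dens)
        cdf /= cdf[-1]
        probs = np.diff(np.interp(edges, theta, np.r_[0, cdf[:-1]]))
        probs /= probs.sum()
        chi2 = np.sum((obs - 10000 * probs)**2 / (10000 * probs))
        # 20 bins -> 19 dof; 1% critical value ~ 36.2
        assert chi2 < 36.2


class TestTiltSeries:
    def test_image_counts(self):
        assert len(tilt_scheme_angles(60, 3)) == 41
        assert len(tilt_scheme_angles(40, 2)) == 41

    def test_bad_scheme(self):
        with pytest.raises(ValueError):
            tilt_scheme_angles(60, 7)
        with pytest.raises(ValueError):
            tilt_scheme_angles(0, 3)

    def test_dose_symmetric_order(self):
        angles = np.array([-6., -3., 0., 3., 6.])
        n = dose_symmetric_order(angles)
        # 0, -3, +3, -6, +6  ->  n = 1..5
        assert n.tolist() == [4, 2, 1, 3, 5]

    def test_zero_tilt_is_axis_sum(self, p1_model):
        vol = build_crystal_density(p1_model, (2, 2, 2), 3.0, 1.0)
        ts = project_tilt_series(vol, 6.0, 3.0)
        i0 = np.flatnonzero(ts.tilt_angles == 0.0)[0]
        assert np.allclose(ts.images[i0], vol.grid.sum(axis=2))

    def test_fourier_slice_theorem(self, p1_model):
        """The 2D transform of each projection matches the central slice of
        the 3D transform at that tilt (correlation > 0.99)."""
        vol = build_crystal_density(p1_model, (2, 2, 2), 3.0, 1.0)
        rot = rotate_volume(vol, random_rotation(5))
        ts = project_tilt_series(rot, 30.0, 15.0)
        F3 = fourier_transform(rot).grid
        n = rot.shape[0]
        c = n // 2
        for img, ang in zip(ts.images, ts.tilt_angles):
            F2 = scipy.fft.fftshift(scipy.fft.fftn(
                np.roll(img, (-c, -c), axis=(0, 1))))
            a = np.deg2rad(ang)
            # sample the 3D transform on the tilted central plane
            ky = np.arange(n) - c
            kx = np.arange(n) - c
            KX, KY = np.meshgrid(kx, ky, indexing="ij")
            ys = KY * np.cos(a) + c
            zs = KY * np.sin(a) + c
            from scipy.ndimage import map_coordinates
            coords = np.array([KX + c, ys, zs])
            re = map_coordinates(F3.real, coords, order=1)
            im = map_coordinates(F3.imag, coords, order=1)
            slice3 = np.abs(re + 1j * im)
            mag2 = np.abs(F2)
            mask = (np.abs(KY) < 0.4 * n) & (np.abs(KX) < 0.4 * n)
            r = np.corrcoef(mag2[mask], slice3[mask])[0, 1]
            assert r > 0.99


class TestReconstruction:
    def test_dense_sampling_limit(self):
        """WBP of a smooth phantom from 1-degree steps over +/-89 degrees
        correlates > 0.95 with the phantom."""
        n = 48
        x, y, z = np.indices((n, n, n)) - n // 2
        phantom = np.exp(-(x**2 + (y - 4)**2 + z**2) / 40.0) \
            + 0.7 * np.exp(-((x + 6)**2 + y**2 + (z - 5)**2) / 25.0)
        vol = Volume(phantom, 1.0)
        ts = project_tilt_series(vol, 89.0, 1.0)
        rec = reconstruct_tomogram(ts, depth=n)
        mask = x**2 + y**2 + z**2 < (n // 2 - 4)**2
        r = np.corrcoef(rec.grid[mask], phantom[mask])[0, 1]
        assert r > 0.95

    def test_missing_wedge_elongation(self, p1_model):
        """A +/-60 degree series elongates density along the beam axis."""
        vol = build_crystal_density(p1_model, (2, 2, 2), 3.0, 1.0)
        ts = project_tilt_series(vol, 60.0, 3.0)
        rec = reconstruct_tomogram(ts, depth=vol.shape[2])
        g = np.clip(rec.grid, 0, None)
        idx = np.indices(g.shape)
        c = (np.array(g.shape) - 1) / 2
        var = [np.average((idx[a] - c[a])**2, weights=g) for a in range(3)]
        # beam axis (z) second moment exceeds the in-plane y moment
        assert var[2] > 1.1 * var[1]

    def test_zero_series_gives_zero(self):
        ts = project_tilt_series(Volume(np.zeros((16, 16, 16)), 1.0), 9, 3)
        rec = reconstruct_tomogram(ts)
        assert np.allclose(rec.grid, 0.0)

    def test_too_few_images(self):
        ts = project_tilt_series(Volume(np.ones((8, 8, 8)), 1.0), 3, 3)
        ts.images = ts.images[:2]
        ts.tilt_angles = ts.tilt_angles[:2]
        ts.acquisition_index = ts.acquisition_index[:2]
        with pytest.raises(ValueError):
            reconstruct_tomogram(ts)


class TestDamage:
    def test_zero_hits_identity(self, p1_model):
        vol = build_crystal_density(p1_model, (2, 2, 2), 3.0, 1.0)
        out = apply_damage_hits(vol, DamageHitModel(0, seed=1))
        assert np.array_equal(out.grid, vol.grid)

    def test_hit_conserves_local_sum(self, p1_model):
        vol = build_crystal_density(p1_model, (2, 2, 2), 3.0, 1.0)
        before = vol.grid.sum()
        out = apply_damage_hits(vol, DamageHitModel(5, seed=3))
        assert out.grid.sum() == pytest.approx(before, rel=0.01)
        assert not np.array_equal(out.grid, vol.grid)

    def test_highres_amplitude_decays_with_hits(self, p1_model):
        """Mean |F| in the 3-4 A shell decreases with hit count (average
        over seeds)."""
        vol = build_crystal_density(p1_model, (2, 2, 2), 3.0, 1.0)
        def shell_amp(v):
            fv = fourier_transform(v)
            q = fv.q_grid()
            shell = (q >= 1 / 4.0) & (q <= 1 / 3.0)
            return np.abs(fv.grid[shell]).mean()
        base = shell_amp(vol)
        means = []
        for hits in (20, 80):
            vals = [shell_amp(apply_damage_hits(
                vol, DamageHitModel(hits, seed=s))) for s in range(6)]
            means.append(np.mean(vals))
        assert base > means[0] > means[1]

    def test_damaged_series_zero_hits_matches_clean(self, p1_model):
        vol = build_crystal_density(p1_model, (2, 2, 2), 3.0, 1.0)
        clean = project_tilt_series(vol, 9.0, 3.0)
        damaged = damaged_tilt_series(vol, 0, 9.0, 3.0, seed=0)
        assert np.allclose(clean.images, damaged.images)

    def test_damage_accumulates_with_acquisition_order(self, p1_model):
        """Projections acquired late differ more from the clean series."""
        vol = build_crystal_density(p1_model, (2, 2, 2), 3.0, 1.0)
        clean = project_tilt_series(vol, 30.0, 3.0)
        damaged = damaged_tilt_series(vol, 30, 30.0, 3.0, seed=4)
        diffs = np.array([np.abs(a - b).sum() for a, b in
                          zip(damaged.images, clean.images)])
        order = damaged.acquisition_index
        first = diffs[order <= 3].mean()
        last = diffs[order > len(order) - 3].mean()
        assert last > first
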