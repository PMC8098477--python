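import numpy as np
import pytest

from nanoxtal.angles import wrap_deg
from nanoxtal.merging import phase_shift
from nanoxtal.origin_search import (centric_residual, expand_to_p1,
                                    find_crystallographic_origin, map_skew,
                                    reduce_to_asu, symmetry_mean_phase,
                                    symmetry_phase_residual)
from nanoxtal.recip_damage import origin_shift_success
from nanoxtal.reflections import ReflectionSet
from nanoxtal.symmetry import UnitCell, unique_reflections


class TestSymmetryMeanPhase:
    def test_p1_returns_own_phase(self, ortho_cell):
        rs = ReflectionSet([[1, 2, 3]], [10.0], [37.0], ortho_cell, "P1")
        assert symmetry_mean_phase(rs, (1, 2, 3)) == pytest.approx(37.0)

    def test_perfect_symmetric_data_agree(self, p212121_reference):
        """On the crystallographic origin all equivalents give the same
        phase estimate."""
        rs = p212121_reference
        for h in [(1, 2, 3), (2, 1, 5), (3, 4, 2)]:
            m = symmetry_mean_phase(rs, h)
            i = rs.index_map()[h]
            assert abs(wrap_deg(m - rs.phase[i])) < 1e-6

    def test_gauge_covariance(self, p212121_reference):
        """Shifting the data off-origin and evaluating at the matching u
        restores agreement."""
        u0 = np.array([0.21, 0.48, 0.77])
        shifted = phase_shift(p212121_reference, u0)
        h = (1, 2, 3)
        i = shifted.index_map()[h]
        m = symmetry_mean_phase(shifted, h, -u0)
        # estimate in the shifted-back gauge equals the unshifted phase
        expect = p212121_reference.phase[p212121_reference.index_map()[h]]
        assert abs(wrap_deg(m - expect)) < 1e-6


class TestSymmetryResidual:
    def test_zero_on_origin(self, p212121_reference):
        assert symmetry_phase_residual(p212121_reference) < 1e-6

    def test_nonzero_off_origin(self, p212121_reference):
        shifted = phase_shift(p212121_reference, (0.21, 0.48, 0.77))
        assert symmetry_phase_residual(shifted) > 20.0
        assert symmetry_phase_residual(
            shifted, (-0.21, -0.48, -0.77) % np.array(1.0)) < 1e-6

    def test_random_phases_match_uniform_expectation(self,
                                                     p212121_reference,
                                                     rng):
        """For uniform random phases the residual matches a Monte-Carlo
        oracle of the same statistic (mean |deviation from the circular
        mean| within equivalence groups; ~45 degrees for pairs)."""
        rs = p212121_reference.copy()
        rs.phase = rng.uniform(-180, 180, len(rs))
        rs.intensity = np.ones(len(rs))
        observed = symmetry_phase_residual(rs)
        # independent oracle: groups of two uniform phases; the deviation
        # from their circular mean is half the wrapped separation
        sep = np.abs((rng.uniform(-180, 180, 200000)
                      - rng.uniform(-180, 180, 200000) + 180) % 360 - 180)
        pair_expect = (sep / 2).mean()   # -> 45 analytically
        assert pair_expect == pytest.approx(45.0, abs=0.5)
        # the data contain groups of 2 and larger, so the residual lies
        # between the pair expectation and the 90-degree upper bound
        assert pair_expect - 5 < observed < 90.0

    def test_periodicity_in_u(self, p212121_reference):
        shifted = phase_shift(p212121_reference, (0.3, 0.1, 0.6))
        r1 = symmetry_phase_residual(shifted, (0.2, 0.4, 0.1))
        r2 = symmetry_phase_residual(shifted, (1.2, -0.6, 2.1))
        assert r1 == pytest.approx(r2, abs=1e-9)

    def test_p1_uninformative(self, ortho_cell):
        rs = ReflectionSet([[1, 0, 0], [0, 1, 0]], [1, 1], [10, 20],
                           ortho_cell, "P1")
        with pytest.raises(ValueError):
            symmetry_phase_residual(rs)


class TestCentricResidual:
    def test_zero_on_origin(self, p212121_reference):
        assert centric_residual(p212121_reference) == pytest.approx(
            0.0, abs=1e-6)

    def test_uniform_phases_expect_45(self, p212121_reference, rng):
        rs = p212121_reference.copy()
        rs.phase = rng.uniform(-180, 180, len(rs))
        rs.intensity = np.ones(len(rs))
        # mean distance of a uniform phase to a 180-degree-spaced set
        assert centric_residual(rs) == pytest.approx(45.0, abs=6.0)

    def test_p1_omitted(self, ortho_cell):
        rs = ReflectionSet([[1, 2, 3]], [1.0], [10.0], ortho_cell, "P1")
        assert np.isnan(centric_residual(rs))


class TestMapSkew:
    def test_correct_phases_positive_skew(self, p212121_reference):
        """A protein-like density has positive skew, so the metric
        (negative skew) is negative for correct phases."""
        assert map_skew(p212121_reference) < -0.5

    def test_random_phases_near_zero_skew(self, p212121_reference, rng):
        rs = p212121_reference.copy()
        rs.phase = rng.uniform(-180, 180, len(rs))
        assert abs(map_skew(rs)) < abs(map_skew(p212121_reference)) / 3

    def test_density_negation_flips_sign(self, p212121_reference):
        rs = p212121_reference.copy()
        # negating the density adds 180 degrees to every phase
        rs.phase = wrap_deg(rs.phase + 180.0)
        assert map_skew(rs) == pytest.approx(-map_skew(p212121_reference),
                                             rel=1e-6)


class TestFindOrigin:
    def test_p1_returns_zero(self, ortho_cell):
        rs = ReflectionSet([[1, 2, 3], [2, 0, 1]], [1, 1], [10, 20],
                           ortho_cell, "P1")
        res = find_crystallographic_origin(rs)
        assert np.allclose(res.shift, 0)
        assert "P1" in res.note

    def test_recovers_known_shift(self, p212121_reference):
        u0 = np.array([0.30, 0.10, 0.70])
        shifted = phase_shift(p212121_reference, u0)
        res = find_crystallographic_origin(shifted, interval=0.2)
        assert origin_shift_success(res.shift, -u0,
                                    p212121_reference.sg, 0.03)

    def test_scores_wrap_invariant(self, p212121_reference):
        shifted = phase_shift(p212121_reference, (0.3, 0.1, 0.7))
        r1 = find_crystallographic_origin(shifted, interval=0.5)
        shifted2 = shifted.copy()
        shifted2.phase = wrap_deg(shifted2.phase + 360.0)
        r2 = find_crystallographic_origin(shifted2, interval=0.5)
        assert np.allclose(r1.shift, r2.shift)

    def test_robust_to_removing_one_metric(self, p212121_reference):
        """Dropping the skew metric still recovers the origin on clean
        data."""
        u0 = np.array([0.25, 0.60, 0.40])
        shifted = phase_shift(p212121_reference, u0)
        res = find_crystallographic_origin(shifted, interval=0.2,
                                           use_skew=False)
        assert origin_shift_success(res.shift, -u0,
                                    p212121_reference.sg, 0.03)


class TestAsuReduction:
    def test_reduced_size_not_larger(self, p212121_reference):
        red = reduce_to_asu(p212121_reference)
        assert len(red) <= len(p212121_reference)
        assert np.all(red.multiplicity >= 1)

    def test_lossless_on_symmetric_data(self, p212121_reference):
        """Reducing then re-expanding perfect data reproduces every
        phase."""
        red = reduce_to_asu(p212121_reference)
        back = expand_to_p1(red)
        ia, ib = p212121_reference.common(back)
        assert len(ia) == len(p212121_reference)
        dev = np.abs(wrap_deg(p212121_reference.phase[ia] - back.phase[ib]))
        assert dev.max() < 1e-6
        assert np.allclose(p212121_reference.intensity[ia],
                           back.intensity[ib], rtol=1e-9)

    def test_residual_zero_after_roundtrip(self, p212121_reference):
        red = reduce_to_asu(p212121_reference)
        back = expand_to_p1(red)
        assert symmetry_phase_residual(back) < 1e-6

    def test_p1_friedel_hemisphere(self, ortho_cell):
        rs = ReflectionSet([[1, 2, 3], [-1, 0, 2]], [1.0, 2.0],
                           [30.0, 70.0], ortho_cell, "P1")
        red = reduce_to_asu(rs)
        seen = {tuple(h) for h in red.hkl}
        # every representative is Friedel-positive (first non-zero index > 0)
        for h in seen:
            first = h[0] if h[0] != 0 else (h[1] if h[1] != 0 else h[2])
            assert first > 0
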