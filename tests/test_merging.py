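import numpy as np
import pytest

from nanoxtal.merging import (merge_datasets, merge_error, origin_alignment,
                              phase_shift, scale_intensities)
from nanoxtal.reflections import ReflectionSet
from nanoxtal.angles import wrap_deg
from nanoxtal.symmetry import UnitCell, unique_reflections


@pytest.fixture(scope="module")
def clean_set():
    cell = UnitCell(16.2, 29.1, 47.7)
    rng = np.random.default_rng(5)
    H = unique_reflections(cell, 4.0)
    return ReflectionSet(H, rng.uniform(1, 100, len(H)),
                         rng.uniform(-180, 180, len(H)), cell)


class TestPhaseShift:
    def test_zero_shift_identity(self, clean_set):
        out = phase_shift(clean_set, (0, 0, 0))
        assert np.allclose(out.phase, clean_set.phase)

    def test_integer_shift_identity(self, clean_set):
        out = phase_shift(clean_set, (1, 0, 0))
        assert np.allclose(wrap_deg(out.phase - clean_set.phase), 0,
                           atol=1e-9)

    def test_half_shift_arithmetic(self, clean_set):
        out = phase_shift(clean_set, (0.5, 0, 0))
        i = clean_set.index_map()[(1, 0, 0)]
        # a -180 degree change wraps onto +180 in the (-180, 180] interval
        assert abs(wrap_deg(out.phase[i] - clean_set.phase[i])) == \
            pytest.approx(180.0)
        j = clean_set.index_map()[(2, 3, -8)]
        # h.u integer -> no change
        assert wrap_deg(out.phase[j] - clean_set.phase[j]) == \
            pytest.approx(0.0, abs=1e-9)

    def test_intensities_unchanged(self, clean_set):
        out = phase_shift(clean_set, (0.37, 0.11, 0.93))
        assert np.array_equal(out.intensity, clean_set.intensity)


class TestOriginAlignment:
    def test_self_alignment_is_zero(self, clean_set):
        u, res = origin_alignment(clean_set, clean_set)
        assert np.allclose(u, 0)
        assert res < 1e-9

    def test_exact_gauge_recovery_on_grid(self, clean_set):
        """Any grid-representable shift is recovered exactly (residual
        below 1e-6 degrees, zero merge error)."""
        from nanoxtal.merging import origin_grid
        fracs, dims = origin_grid(clean_set.cell, 0.2)
        u_true = np.array([fracs[0][20], fracs[1][7], fracs[2][101]])
        shifted = phase_shift(clean_set, u_true)
        u, res = origin_alignment(clean_set, shifted, interval=0.2)
        assert res < 1e-6
        assert merge_error(u, u_true) == pytest.approx(0.0, abs=1e-12)

    def test_offgrid_shift_recovered_to_grid_resolution(self, clean_set):
        u_true = np.array([0.311, 0.107, 0.703])
        shifted = phase_shift(clean_set, u_true)
        u, _ = origin_alignment(clean_set, shifted, interval=0.2)
        assert merge_error(u, u_true) < 0.02

    def test_noisy_recovery_rate(self, clean_set):
        """With 20 degree Gaussian phase noise the shift is recovered
        within 0.03 fractional error in >= 95% of seeds."""
        rng = np.random.default_rng(77)
        ok = 0
        n = 40
        for _ in range(n):
            u_true = rng.random(3)
            noisy = phase_shift(clean_set, u_true)
            noisy.phase = wrap_deg(noisy.phase + rng.normal(0, 20,
                                                            len(noisy)))
            u, _ = origin_alignment(clean_set, noisy, interval=0.2)
            ok += merge_error(u, u_true) < 0.03
        assert ok >= int(np.ceil(0.95 * n))

    def test_disjoint_sets_error(self, clean_set):
        a = clean_set.select(np.arange(10))
        b = clean_set.select(np.arange(20, 30))
        with pytest.raises(ValueError, match="disjoint|shared"):
            origin_alignment(a, b)

    def test_shortlist_matches_exhaustive(self, clean_set):
        """The FFT-shortlisted search returns the exhaustive argmin."""
        rng = np.random.default_rng(3)
        small = clean_set.select(np.arange(0, len(clean_set), 3))
        u_true = rng.random(3)
        noisy = phase_shift(small, u_true)
        noisy.phase = wrap_deg(noisy.phase + rng.normal(0, 30, len(noisy)))
        # coarse interval keeps the exhaustive grid tractable
        u_fast, r_fast = origin_alignment(small, noisy, interval=0.8,
                                          method="auto")
        u_grid, r_grid = origin_alignment(small, noisy, interval=0.8,
                                          method="grid")
        assert np.allclose(u_fast, u_grid)
        assert r_fast == pytest.approx(r_grid)


class TestScaling:
    def test_identity(self, clean_set):
        params, scaled = scale_intensities(clean_set, clean_set)
        assert params.m == pytest.approx(0.0, abs=1e-9)
        assert params.b == pytest.approx(0.0, abs=1e-9)
        assert params.sigma == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(scaled.intensity, clean_set.intensity, rtol=1e-6)

    def test_debye_waller_recovery(self, clean_set):
        """An injected Debye-Waller decay with sigma = 5 A is recovered
        within 5% and divided back out."""
        s = 5.0
        q = clean_set.q()
        other = clean_set.copy()
        other.intensity = other.intensity * np.exp(-q**2 * s**2 / 2.0)
        params, scaled = scale_intensities(clean_set, other)
        assert params.sigma == pytest.approx(s, rel=0.05)
        assert np.allclose(scaled.intensity, clean_set.intensity, rtol=1e-6)

    def test_constant_scale_recovery(self, clean_set):
        other = clean_set.copy()
        other.intensity = 2.0 * other.intensity
        params, scaled = scale_intensities(clean_set, other)
        assert params.b == pytest.approx(np.log(2.0), abs=1e-9)
        assert abs(params.m) < 1e-9
        assert np.allclose(scaled.intensity, clean_set.intensity, rtol=1e-6)

    def test_too_few_pairs(self, clean_set):
        a = clean_set.select(np.arange(3))
        with pytest.raises(ValueError):
            scale_intensities(a, a)


class TestMergeDatasets:
    def test_self_merge_doubles_multiplicity(self, clean_set):
        merged, shifts = merge_datasets([clean_set, clean_set.copy()])
        assert len(merged) == len(clean_set)
        assert np.all(merged.multiplicity == 2)
        assert np.allclose(wrap_deg(merged.phase - clean_set.phase), 0,
                           atol=1e-6)
        assert np.allclose(shifts[0], 0)

    def test_union_increases_completeness(self, clean_set):
        """Merging partial random subsets yields a larger set than any
        input."""
        rng = np.random.default_rng(9)
        subsets = []
        for k in range(4):
            mask = rng.random(len(clean_set)) < 0.4
            subsets.append(clean_set.select(mask))
        merged, _ = merge_datasets(subsets)
        assert len(merged) > max(len(s) for s in subsets)

    def test_phase_averaging_beats_single_set(self, clean_set):
        """Merged phases of noisy shifted copies are closer to the truth
        than any single input."""
        rng = np.random.default_rng(21)
        sets = []
        for k in range(5):
            u = rng.random(3)
            s = phase_shift(clean_set, u)
            s.phase = wrap_deg(s.phase + rng.normal(0, 15, len(s)))
            sets.append(s)
        merged, shifts = merge_datasets(sets)
        ref0 = clean_set  # noise-free truth (arbitrary gauge)
        # merged lives on set 0's origin; realign everything to the truth
        u0, _ = origin_alignment(ref0, merged)
        aligned = phase_shift(merged, -u0)
        ia, ib = ref0.common(aligned)
        err_merged = np.abs(wrap_deg(ref0.phase[ia]
                                     - aligned.phase[ib])).mean()
        errs_single = []
        for s in sets:
            us, _ = origin_alignment(ref0, s)
            al = phase_shift(s, -us)
            ia, ib = ref0.common(al)
            errs_single.append(np.abs(wrap_deg(ref0.phase[ia]
                                               - al.phase[ib])).mean())
        assert err_merged < min(errs_single)


class TestMergeError:
    @pytest.mark.parametrize("a,b,expected", [
        ((0.2, 0.3, 0.4), (0.2, 0.3, 0.4), 0.0),
        ((0.99, 0, 0), (0.01, 0, 0), 0.02),
        ((0.5, 0.5, 0.5), (0, 0, 0), np.sqrt(0.75)),
    ])
    def test_examples(self, a, b, expected):
        assert merge_error(a, b) == pytest.approx(expected, abs=1e-12)

    def test_symmetry(self, rng):
        for _ in range(20):
            a, b = rng.random(3), rng.random(3)
            assert merge_error(a, b) == pytest.approx(merge_error(b, a))
            assert merge_error(a, b) <= np.sqrt(0.75) + 1e-12
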