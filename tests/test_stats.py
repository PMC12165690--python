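import numpy as np
import pingouin
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from crpnet.stats import (
    DiagonalConvergence, band_jaccard_matrix, bayes_paired_ttest_bf01, bf01_from_t,
    diagonal_profile, edge_temporal_convergence, jaccard, on_off_ratio,
    static_crossmodal_similarity, subject_nonparametric_p,
)

from conftest import make_frames


class TestOnOffRatio:
    def test_all_true_matrix(self):
        assert on_off_ratio(np.ones((20, 20), bool), 0) == pytest.approx(1.0)

    def test_counting_oracle_10x10(self, rng):
        m = np.zeros((10, 10), dtype=bool)
        diag_idx = rng.choice(10, 5, replace=False)
        m[diag_idx, diag_idx] = True  # diagonal rate 0.5
        off_cells = [(i, j) for i in range(10) for j in range(10) if i != j]
        pick = rng.choice(len(off_cells), 90 // 4, replace=False)
        for k in pick:
            m[off_cells[k]] = True  # off rate ~0.25
        expected = (5 / 10) / (len(pick) / 90)
        assert on_off_ratio(m, 0) == pytest.approx(expected)

    def test_shifted_diagonal(self):
        m = np.zeros((12, 12), dtype=bool)
        idx = np.arange(10)
        m[idx, idx + 2] = True
        m[0, 5] = True  # off-diagonal content so the ratio is defined
        r = on_off_ratio(m, 2)
        assert r > 10  # on rate 1.0, off rate tiny

    def test_corner_entries_excluded_from_both_counts(self):
        # with shift 2 on a 6x6 CRP, only the 4x4 aligned submatrix counts
        m = np.zeros((6, 6), dtype=bool)
        m[np.arange(4), np.arange(4) + 2] = True
        m[5, 0] = True  # in a cut corner: must not count as off-diagonal
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(on_off_ratio(m, 2))

    def test_zero_off_rate_undefined(self):
        m = np.eye(10, dtype=bool)
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(on_off_ratio(m, 0))

    def test_density_matched_random_near_unity(self, rng):
        vals = [on_off_ratio(rng.random((100, 100)) < 0.3, 0) for _ in range(100)]
        assert np.mean(vals) == pytest.approx(1.0, abs=0.05)


class TestDiagonalProfile:
    def test_zero_shift_consistency(self, rng):
        layers = rng.random((30, 30, 2)) < 0.25
        prof = diagonal_profile(layers, shifts=(-1, 0, 1), n_null=30, seed=0)
        assert prof.ratios[1] == pytest.approx(on_off_ratio(layers.any(2), 0))

    def test_random_matrix_no_significant_shift(self, rng):
        layers = rng.random((40, 40, 1)) < 0.3
        prof = diagonal_profile(layers, shifts=range(-5, 6), n_null=50, seed=1)
        assert np.sum(prof.p_values < 0.05) <= 2

    def test_null_ensemble_shape_and_center(self, rng):
        layers = rng.random((40, 40, 2)) < 0.2
        prof = diagonal_profile(layers, shifts=(0,), n_null=60, seed=2)
        assert prof.null_ratios.shape == (60, 1)
        assert np.nanmean(prof.null_ratios) == pytest.approx(1.0, abs=0.1)

    def test_estimator_wrapper(self, rng):
        layers = rng.random((30, 30, 1)) < 0.25
        est = DiagonalConvergence(shifts=(0, 1), n_null=25, random_state=0).fit(layers)
        assert est.ratios_.shape == (2,)
        np.testing.assert_array_equal(est.ratios_, est.profile_.ratios)

    def test_too_small_crp_rejected(self, rng):
        with pytest.raises(ValueError):
            diagonal_profile(rng.random((8, 8, 1)) < 0.5, shifts=range(-7, 8))


class TestNonparametricP:
    def test_above_all_nulls(self):
        assert subject_nonparametric_p(1000.0, np.arange(100)) == pytest.approx(1 / 101)

    def test_at_null_median(self):
        nulls = np.linspace(0, 1, 101)
        assert subject_nonparametric_p(0.5, nulls) == pytest.approx(0.5, abs=0.02)

    def test_requires_enough_nulls(self):
        with pytest.raises(ValueError):
            subject_nonparametric_p(1.0, np.arange(5))


class TestBayesFactor:
    def test_null_favoring_at_t_zero(self):
        assert bf01_from_t(0.0, 9) > 1.0

    def test_symmetry_identity_vs_pingouin(self):
        # two-sided JZS BF10 = average of the two one-sided BF10s
        for t, n in [(0.0, 9), (1.3, 9), (2.5, 12), (-0.8, 26)]:
            two_sided = float(pingouin.bayesfactor_ttest(t, n, paired=True, r=0.707))
            combined = 0.5 * (1 / bf01_from_t(t, n) + 1 / bf01_from_t(-t, n))
            assert combined == pytest.approx(two_sided, rel=1e-6)

    def test_scale_invariance(self, rng):
        obs = rng.random(8) + 1.0
        null = rng.random(8) + 1.0
        a = bayes_paired_ttest_bf01(obs, null)
        b = bayes_paired_ttest_bf01(10.0 * obs, 10.0 * null)
        assert a == pytest.approx(b, rel=1e-9)

    def test_monotone_in_effect_direction(self, rng):
        null = rng.random(10)
        noise = rng.standard_normal(10) * 0.1
        bfs = [bayes_paired_ttest_bf01(null + noise + d, null) for d in (0.0, 0.3, 0.8)]
        assert bfs[0] > bfs[1] > bfs[2]

    def test_degenerate_differences_flagged(self):
        with pytest.raises(ValueError, match="degenerate"):
            bayes_paired_ttest_bf01(np.ones(5) + 1.0, np.ones(5))


class TestJaccard:
    def test_worked_examples(self):
        a = np.array([1, 1, 0, 0], bool)
        b = np.array([1, 0, 1, 0], bool)
        assert jaccard(a, b) == pytest.approx(1 / 3)
        assert jaccard(a, a) == 1.0
        assert jaccard(a, ~a) == 0.0

    def test_both_empty_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(jaccard(np.zeros(4, bool), np.zeros(4, bool)))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(hst.lists(hst.booleans(), min_size=4, max_size=40),
           hst.lists(hst.booleans(), min_size=4, max_size=40))
    def test_symmetry_and_density_bound(self, xs, ys):
        n = min(len(xs), len(ys))
        a, b = np.array(xs[:n]), np.array(ys[:n])
        if not (a | b).any():
            return
        j_ab = jaccard(a, b)
        assert j_ab == jaccard(b, a)
        if a.any() and b.any():
            dens = sorted([a.mean(), b.mean()])
            assert j_ab <= dens[0] / dens[1] + 1e-12

    def test_band_matrix(self, rng):
        layers = rng.random((20, 20, 3)) < 0.3
        df = band_jaccard_matrix(layers, ["delta", "alpha", "gamma"])
        assert df.shape == (3, 3)
        assert np.allclose(np.diag(df), 1.0)
        assert df.loc["delta", "alpha"] == df.loc["alpha", "delta"]


class TestStaticSimilarity:
    def test_identical_and_flipped(self, rng):
        v = rng.standard_normal(30)
        assert static_crossmodal_similarity(v, v) == pytest.approx(1.0)
        assert static_crossmodal_similarity(v, -v) == pytest.approx(-1.0)

    def test_toy_value(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([1.0, 3.0, 2.0, 4.0])
        assert static_crossmodal_similarity(a, b) == pytest.approx(
            np.corrcoef(a, b)[0, 1])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            static_crossmodal_similarity(np.ones(3), np.ones(4))


class TestEdgeTemporalConvergence:
    def test_identical_series_fully_significant(self, rng):
        frames = rng.standard_normal((40, 21))
        fmri = make_frames(frames, 7)
        eeg = make_frames(frames.copy(), 7, coupling="amp")
        r, p, sig = edge_temporal_convergence(fmri, eeg, n_perm=50, seed=0)
        np.testing.assert_allclose(r, 1.0, atol=1e-12)
        assert sig.all()

    def test_independent_series_controls_fdr(self, rng):
        fmri = make_frames(rng.standard_normal((60, 45)), 10)
        eeg = make_frames(rng.standard_normal((60, 45)), 10, coupling="amp")
        _, _, sig = edge_temporal_convergence(fmri, eeg, n_perm=100, q=0.05, seed=1)
        assert sig.mean() <= 0.1

    def test_short_series_rejected(self, rng):
        f = make_frames(rng.standard_normal((5, 10)), 5)
        with pytest.raises(ValueError):
            edge_temporal_convergence(f, f, n_perm=20)
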