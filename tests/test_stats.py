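import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from itwater import (
    DegenerateSampleError,
    Sample,
    filliben_quantiles,
    holm_bonferroni,
    normality_screen,
    probability_plot_r2,
    shapiro_wilk,
    summarize_distribution,
    welch_t,
)


class TestShapiroWilk:
    def test_three_point_sample_attains_w_of_one(self):
        # for n=3, a1 = sqrt(1/2): numerator (a1*(x3-x1))^2 = 2 = SSE for {1,2,3}
        res = shapiro_wilk([1.0, 2.0, 3.0])
        assert res.W == pytest.approx(1.0, abs=1e-12)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=25)
        a = shapiro_wilk(x)
        b = shapiro_wilk(5.0 - 3.0 * x)
        assert a.W == pytest.approx(b.W, rel=1e-12)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-9)

    def test_matches_reference_implementation(self, rng):
        """Oracle equivalence against scipy on 50 mixed-shape fixtures."""
        for trial in range(50):
            n = int(rng.integers(4, 60))
            x = {
                0: rng.normal(size=n),
                1: rng.exponential(size=n),
                2: rng.uniform(size=n) ** 3,
            }[trial % 3]
            mine = shapiro_wilk(x)
            ref_w, ref_p = sps.shapiro(x)
            assert mine.W == pytest.approx(ref_w, abs=1e-6)
            assert mine.p_value == pytest.approx(ref_p, abs=1e-4)

    def test_rejects_out_of_range_n(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])

    def test_zero_variance_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            shapiro_wilk([2.0, 2.0, 2.0, 2.0])

    def test_type_one_error_near_nominal(self):
        """Rejection rate on true normal samples stays at the 5% level."""
        rng = np.random.default_rng(7)
        n_rep, n = 2000, 20
        rejections = sum(
            shapiro_wilk(rng.normal(size=n)).p_value < 0.05 for _ in range(n_rep)
        )
        rate = rejections / n_rep
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) < 3.3 * se


class TestFilliben:
    def test_n3_values(self):
        p = filliben_quantiles(3)
        assert p == pytest.approx([1 - 0.5 ** (1 / 3), (2 - 0.3175) / 3.365, 0.5 ** (1 / 3)])
        assert p == pytest.approx([0.20630, 0.5, 0.79370], abs=5e-6)

    def test_n2_edge_branches(self):
        assert filliben_quantiles(2) == pytest.approx([0.29289, 0.70711], abs=5e-6)

    def test_n_below_two_rejected(self):
        with pytest.raises(ValueError):
            filliben_quantiles(1)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(n=st.integers(2, 10_000))
    def test_increasing_and_symmetric(self, n):
        p = filliben_quantiles(n)
        assert np.all(np.diff(p) > 0)
        assert np.allclose(p + p[::-1], 1.0, atol=1e-12)


class TestProbabilityPlot:
    def test_perfectly_normal_quantiles_give_r2_one(self):
        q = sps.norm.ppf(filliben_quantiles(20))
        assert probability_plot_r2(q) == pytest.approx(1.0, abs=1e-12)

    def test_bimodal_sample_fails_screen(self, rng):
        x = np.concatenate([rng.normal(-5, 0.25, 15), rng.normal(5, 0.25, 15)])
        assert probability_plot_r2(x) < 0.9

    def test_affine_invariance(self, rng):
        x = rng.normal(size=30)
        assert probability_plot_r2(x) == pytest.approx(
            probability_plot_r2(2.5 * x - 7), rel=1e-12
        )

    def test_verdict_encodes_conjunction(self, rng):
        good = rng.normal(size=40)
        res = normality_screen(good)
        assert res.verdict == ("normal-supported" if res.p_value > 0.05 and res.r_squared > 0.9 else "rejected")
        bimodal = np.concatenate([rng.normal(-5, 0.25, 20), rng.normal(5, 0.25, 20)])
        assert normality_screen(bimodal).verdict == "rejected"


class TestWelch:
    def test_identical_samples(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0
        assert res.p_value == pytest.approx(1.0)
        assert not res.significant

    def test_hand_computed_example(self):
        res = welch_t([1, 2, 3], [2, 3, 4])
        assert res.t == pytest.approx(-1.22474487, abs=1e-8)
        assert res.df == pytest.approx(4.0, abs=1e-12)

    def test_matches_reference_implementation(self, rng):
        for _ in range(50):
            a = rng.normal(0, 1, size=int(rng.integers(5, 40)))
            b = rng.normal(0.3, 2, size=int(rng.integers(5, 40)))
            mine = welch_t(a, b)
            ref = sps.ttest_ind(a, b, equal_var=False)
            assert mine.t == pytest.approx(ref.statistic, abs=1e-6)
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-4)
            assert mine.df == pytest.approx(ref.df, abs=1e-6)

    def test_df_within_satterthwaite_bounds(self, rng):
        for _ in range(30):
            a = rng.normal(size=int(rng.integers(3, 20)))
            b = rng.normal(size=int(rng.integers(3, 20)))
            res = welch_t(a, b)
            assert min(a.size, b.size) - 1 <= res.df <= a.size + b.size - 2 + 1e-9

    def test_both_zero_variance_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            welch_t([1.0, 1.0], [2.0, 2.0])

    def test_type_one_error_under_unequal_variances(self):
        """10,000-rep null simulation (equal means, sigma^2 = 1 vs 4, n=15):
        the rejection rate stays at the nominal 5% level."""
        rng = np.random.default_rng(11)
        n_rep = 10_000
        a = rng.normal(0, 1, size=(n_rep, 15))
        b = rng.normal(0, 2, size=(n_rep, 15))
        rejections = sum(welch_t(a[i], b[i]).significant for i in range(n_rep))
        rate = rejections / n_rep
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) < 3.3 * se


class TestSummaries:
    def test_quartiles_of_one_to_hundred(self):
        s = summarize_distribution(np.arange(1.0, 101.0))
        assert s.median == pytest.approx(50.5)
        assert s.q1 == pytest.approx(25.75)  # linear interpolation convention
        assert s.q3 == pytest.approx(75.25)
        assert s.outliers == ()

    def test_constant_sample(self):
        s = summarize_distribution([4.0, 4.0, 4.0])
        assert s.q3 - s.q1 == 0.0
        assert s.outliers == ()
        assert s.whisker_low == s.whisker_high == 4.0

    def test_injected_extreme_point_flagged(self):
        x = np.concatenate([np.linspace(0, 1, 20), [50.0]])
        s = summarize_distribution(x)
        assert s.outliers == (50.0,)
        assert s.whisker_high <= 1.0

    def test_labeled_sample_accepted(self):
        s = Sample(values=np.arange(10.0), model="SPC", size=1, space="r", measure="S")
        assert summarize_distribution(s).median == pytest.approx(4.5)


class TestHolm:
    def test_stepdown_rejects_only_smallest(self):
        reject = holm_bonferroni([0.001, 0.04, 0.2])
        assert list(reject) == [True, False, False]
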