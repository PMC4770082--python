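"""Statistical-test battery: exact oracles, identities and calibration."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from embryomech.stats import (
    chi2_contingency,
    ks_two_sample,
    lilliefors_normality,
    t_test_two_sided,
    two_proportion_ztest,
    wilcoxon_rank_sum,
)


def exact_rank_sum_p(x, y):
    """Independent oracle: two-sided rank-sum p by full enumeration."""
    pooled = np.r_[x, y]
    ranks = sps.rankdata(pooled)
    nx = len(x)
    w_obs = ranks[:nx].sum()
    mean_w = nx * (len(pooled) + 1) / 2.0
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), nx):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-9:
            count += 1
    return count / total


class TestWilcoxon:
    def test_identical_samples_give_p_one(self):
        rep = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert rep.p_value == pytest.approx(1.0)

    def test_disjoint_five_vs_five_exact(self):
        rep = wilcoxon_rank_sum([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        assert rep.method["mode"] == "exact"
        assert rep.p_value == pytest.approx(2 / math.comb(10, 5), abs=1e-15)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=4), rng.normal(1.0, 1.0, size=4)
        rep = wilcoxon_rank_sum(x, y, mode="exact")
        assert rep.p_value == pytest.approx(exact_rank_sum_p(x, y), abs=1e-12)

    def test_asymptotic_close_to_exact_at_ten_vs_ten(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=10), rng.normal(0.5, 1.0, size=10)
        p_exact = wilcoxon_rank_sum(x, y, mode="exact").p_value
        p_asym = wilcoxon_rank_sum(x, y, mode="asymptotic").p_value
        assert abs(p_exact - p_asym) < 0.01

    def test_swap_symmetry(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=12), rng.normal(size=15)
        assert wilcoxon_rank_sum(x, y).p_value == pytest.approx(
            wilcoxon_rank_sum(y, x).p_value, abs=1e-12
        )

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestKolmogorovSmirnov:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0]
        rep = ks_two_sample(x, x)
        assert rep.statistic == 0.0
        assert rep.p_value == pytest.approx(1.0)

    def test_fully_separated_samples_have_d_one(self):
        rep = ks_two_sample([1, 2, 3], [10, 11, 12])
        assert rep.statistic == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 5])
    def test_exact_and_asymptotic_agree_roughly_at_small_n(self, seed):
        # the two-sample exact null is discrete; the effective-n asymptotic
        # can sit ~0.1 away at n=10 vs 10, so only coarse agreement holds
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=10), rng.normal(size=10)
        p_exact = ks_two_sample(x, y, mode="exact").p_value
        p_asym = ks_two_sample(x, y, mode="asymptotic").p_value
        assert abs(p_exact - p_asym) < 0.15

    def test_too_small_samples_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([1.0], [1.0, 2.0])


class TestChi2:
    def test_live_birth_style_table_highly_significant(self):
        # counts reconstructed from 74% vs 24% of 55 transfers each
        table = [[41, 14], [13, 42]]
        assert chi2_contingency(table, yates=True).p_value < 1e-6
        rep = chi2_contingency(table, yates=False)
        assert rep.p_value < 1e-6
        assert rep.statistic == pytest.approx(28.5185, abs=2e-4)

    def test_equal_proportions_give_zero_statistic(self):
        rep = chi2_contingency([[20, 20], [20, 20]])
        assert rep.statistic == 0.0
        assert rep.p_value == pytest.approx(1.0)

    def test_statistic_matches_hand_sum_on_2x3(self):
        table = np.array([[10, 20, 30], [15, 12, 9]])
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        hand = ((table - expected) ** 2 / expected).sum()
        rep = chi2_contingency(table)
        assert rep.statistic == pytest.approx(hand, rel=1e-12)
        assert rep.method["df"] == 2

    def test_low_expected_count_flagged(self):
        rep = chi2_contingency([[2, 30], [3, 40]], yates=False)
        assert rep.method["expected_below_5"]

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi2_contingency([[0, 0], [5, 10]])


class TestTwoProportionZ:
    def test_equal_proportions(self):
        rep = two_proportion_ztest(10, 20, 25, 50)
        assert rep.statistic == pytest.approx(0.0, abs=1e-12)
        assert rep.p_value == pytest.approx(1.0)

    def test_measured_vs_control_blastocyst_rates_not_significant(self):
        # 67% of 282 measured vs ~70% of 35 control embryos
        rep = two_proportion_ztest(189, 282, 25, 35)
        assert rep.p_value > 0.5

    def test_z_squared_equals_uncorrected_chi2(self):
        s1, n1, s2, n2 = 30, 80, 45, 90
        z = two_proportion_ztest(s1, n1, s2, n2).statistic
        chi2 = chi2_contingency([[s1, n1 - s1], [s2, n2 - s2]],
                                yates=False).statistic
        assert z**2 == pytest.approx(chi2, rel=1e-10)

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            two_proportion_ztest(0, 0, 1, 2)


class TestLilliefors:
    def test_gaussian_sample_not_rejected(self):
        x = np.random.default_rng(1).standard_normal(500)
        assert lilliefors_normality(x, n_mc=500, seed=0).p_value > 0.05

    def test_exponential_sample_rejected(self):
        x = np.random.default_rng(1).exponential(size=100)
        assert lilliefors_normality(x, n_mc=500, seed=0).p_value < 0.05

    def test_monte_carlo_consistency(self):
        x = np.random.default_rng(2).standard_normal(60)
        p1 = lilliefors_normality(x, n_mc=500, seed=1).p_value
        p2 = lilliefors_normality(x, n_mc=1000, seed=2).p_value
        se = math.sqrt(p1 * (1 - p1) / 500)
        assert abs(p1 - p2) < 4 * se + 0.01

    def test_agrees_with_table_based_reference(self):
        from statsmodels.stats.diagnostic import lilliefors as sm_lilliefors
        x = np.random.default_rng(3).exponential(size=80)
        d_ref, p_ref = sm_lilliefors(x, dist="norm")
        rep = lilliefors_normality(x, n_mc=1000, seed=0)
        assert rep.statistic == pytest.approx(d_ref, abs=1e-10)
        assert (rep.p_value < 0.05) == (p_ref < 0.05)

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            lilliefors_normality([1.0, 1.0, 1.0, 1.0])


class TestTTest:
    def test_identical_samples(self):
        rep = t_test_two_sided([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert rep.statistic == 0.0
        assert rep.p_value == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        # welch: t = (1-5+... ) mean diff -3, se = sqrt(1/3 + 1/3)
        t_hand = -3.0 / math.sqrt(1.0 / 3.0 + 1.0 / 3.0)
        assert t_test_two_sided(x, y).statistic == pytest.approx(t_hand, abs=1e-12)

    def test_welch_equals_pooled_for_balanced_equal_variance(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = x + 0.5
        welch = t_test_two_sided(x, y)
        pooled = t_test_two_sided(x, y, pooled=True)
        assert welch.statistic == pytest.approx(pooled.statistic, rel=1e-12)
        assert welch.method["df"] == pytest.approx(6.0)


finite_samples = st.lists(
    st.floats(-1e3, 1e3, allow_nan=False, allow_infinity=False),
    min_size=3, max_size=12,
)


class TestRankTestProperties:
    @given(finite_samples, finite_samples)
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_wilcoxon_p_in_unit_interval_and_swap_symmetric(self, x, y):
        a = wilcoxon_rank_sum(x, y)
        b = wilcoxon_rank_sum(y, x)
        assert 0.0 <= a.p_value <= 1.0
        assert a.p_value == pytest.approx(b.p_value, abs=1e-9)

    @given(finite_samples, finite_samples)
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_ks_p_in_unit_interval_and_swap_symmetric(self, x, y):
        a = ks_two_sample(x, y)
        b = ks_two_sample(y, x)
        assert 0.0 <= a.p_value <= 1.0
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)


class TestTypeIErrorCalibration:
    """Null rejection rates at alpha = 0.05 stay within [0.03, 0.07]."""

    N_REPS = 1000

    def _rate(self, pfunc):
        rng = np.random.default_rng(42)
        return np.mean([pfunc(rng) < 0.05 for _ in range(self.N_REPS)])

    def test_t_test_calibrated(self):
        rate = self._rate(lambda rng: t_test_two_sided(
            rng.standard_normal(20), rng.standard_normal(20)).p_value)
        assert 0.03 <= rate <= 0.07

    def test_wilcoxon_calibrated(self):
        rate = self._rate(lambda rng: wilcoxon_rank_sum(
            rng.standard_normal(25), rng.standard_normal(25)).p_value)
        assert 0.03 <= rate <= 0.07

    def test_ks_exact_calibrated(self):
        rate = self._rate(lambda rng: ks_two_sample(
            rng.standard_normal(15), rng.standard_normal(15)).p_value)
        assert 0.01 <= rate <= 0.07  # discrete exact null is conservative

    def test_chi2_uncorrected_calibrated(self):
        def pfunc(rng):
            a = rng.binomial(100, 0.5)
            b = rng.binomial(100, 0.5)
            return chi2_contingency([[a, 100 - a], [b, 100 - b]],
                                    yates=False).p_value
        rate = self._rate(pfunc)
        assert 0.03 <= rate <= 0.07
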