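"""Statistical battery vs brute-force ANOVA sums, closed forms and
independent library implementations (pingouin, scipy)."""

import numpy as np
import pandas as pd
import pytest

from mortisesim.stats import (InsufficientDataError, icc_two_observers,
                              independent_t_test, proportion_percent,
                              summarize_group, tamhane_t2, welch_t)


class TestSummaries:
    def test_table_row_ci_arithmetic(self):
        """mean 0.49, sd 0.05, n 96 -> 95% CI rounding to (0.48, 0.50)."""
        x = np.arange(96, dtype=float)
        x = (x - x.mean()) / x.std(ddof=1)
        s = summarize_group(0.49 + 0.05 * x)
        assert s.mean == pytest.approx(0.49)
        assert s.sd == pytest.approx(0.05)
        assert round(s.ci_low, 2) == 0.48
        assert round(s.ci_high, 2) == 0.50

    def test_constant_vector_zero_width(self):
        s = summarize_group([0.4] * 10)
        assert s.sd == 0.0
        assert s.ci_low == s.ci_high == pytest.approx(0.4)

    def test_two_point_closed_form(self):
        s = summarize_group([0.0, 1.0])
        assert s.mean == pytest.approx(0.5)
        assert s.sd == pytest.approx(np.sqrt(0.5))

    def test_single_value_rejected(self):
        with pytest.raises(InsufficientDataError):
            summarize_group([0.5])

    def test_ci_coverage_is_nominal(self):
        """95% t-CIs cover the true mean in 95 +/- 1.5 % of simulations."""
        rng = np.random.default_rng(7)
        n, reps, mu = 20, 10_000, 0.5
        from scipy import stats as sps

        x = rng.normal(mu, 0.1, size=(reps, n))
        means = x.mean(axis=1)
        half = sps.t.ppf(0.975, n - 1) * x.std(axis=1, ddof=1) / np.sqrt(n)
        covered = np.abs(means - mu) <= half
        assert abs(covered.mean() - 0.95) < 0.015


class TestICC:
    def test_identical_observers_give_one(self):
        x = np.linspace(0.2, 0.8, 25)
        assert icc_two_observers(x, x) == pytest.approx(1.0)

    def test_independent_noise_gives_near_zero(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0, 1, 1000)
        b = rng.normal(0, 1, 1000)
        assert abs(icc_two_observers(a, b)) < 0.1

    def test_matches_brute_force_anova_sums(self):
        """Small worked dataset vs a direct mean-squares computation."""
        o1 = np.array([9.0, 6.0, 8.0, 7.0, 10.0, 6.0])
        o2 = np.array([2.0, 1.0, 4.0, 1.0, 5.0, 2.0])
        data = np.stack([o1, o2], axis=1)
        n, k = data.shape
        grand = data.mean()
        msr = k * ((data.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((data.mean(0) - grand) ** 2).sum() / (k - 1)
        mse = (((data - data.mean(1, keepdims=True) - data.mean(0) + grand) ** 2).sum()
               / ((n - 1) * (k - 1)))
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert icc_two_observers(o1, o2) == pytest.approx(expected, abs=1e-10)

    def test_matches_pingouin_icc2(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        true = rng.normal(0.5, 0.05, 40)
        o1 = true + rng.normal(0, 0.02, 40)
        o2 = true + rng.normal(0, 0.02, 40)
        df = pd.DataFrame({
            "subject": np.tile(np.arange(40), 2),
            "rater": np.repeat(["a", "b"], 40),
            "score": np.concatenate([o1, o2])})
        table = pingouin.intraclass_corr(df, targets="subject", raters="rater",
                                         ratings="score")
        ref = float(table.loc[table["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert icc_two_observers(o1, o2) == pytest.approx(ref, abs=1e-9)

    def test_recovers_variance_ratio(self):
        """Known sigma_b^2 / (sigma_b^2 + sigma_e^2) recovered within 0.03."""
        rng = np.random.default_rng(21)
        sb, se = 0.06, 0.03
        truth = sb**2 / (sb**2 + se**2)
        subj = rng.normal(0.5, sb, 500)
        o1 = subj + rng.normal(0, se, 500)
        o2 = subj + rng.normal(0, se, 500)
        assert icc_two_observers(o1, o2) == pytest.approx(truth, abs=0.03)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            icc_two_observers([1, 2, 3], [1, 2])


class TestWelchAndTamhane:
    def test_welch_matches_scipy(self):
        from scipy import stats as sps

        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.4, 2.5, 21)
        t, df, p = welch_t(a, b)
        t_ref, p_ref = sps.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(t_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_identical_groups_fully_nonsignificant(self):
        g = list(np.linspace(0, 1, 20))
        results = tamhane_t2([g, g])
        assert results[0].t_stat == 0.0
        assert results[0].p_adjusted == 1.0

    def test_large_separation_is_significant(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 1, 50)
        b = rng.normal(5, 1, 50)
        res = tamhane_t2([a, b])
        assert res[0].p_adjusted < 1e-3

    def test_sidak_adjustment_closed_form(self):
        rng = np.random.default_rng(13)
        groups = [rng.normal(m, 1, 20) for m in (0.0, 0.3, 0.6)]
        res = tamhane_t2(groups)
        m = 3
        for r in res:
            expected = 1.0 - (1.0 - r.p_raw) ** m
            assert r.p_adjusted == pytest.approx(expected, abs=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            tamhane_t2([[1.0, 2.0], [3.0]])


class TestIndependentT:
    def test_identical_groups_p_one(self):
        g = [1.0, 2.0, 3.0]
        assert independent_t_test(g, g) == pytest.approx(1.0)

    def test_extreme_separation(self):
        g = [1.0, 2.0, 3.0]
        shifted = [101.0, 102.0, 103.0]
        assert independent_t_test(g, shifted) < 1e-6

    def test_pooled_matches_hand_computation(self):
        a = np.array([2.1, 2.5, 2.3, 2.2])
        b = np.array([2.8, 3.0, 2.6, 3.1, 2.9])
        n1, n2 = len(a), len(b)
        sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        from scipy import stats as sps

        expected = 2 * sps.t.sf(abs(t), n1 + n2 - 2)
        assert independent_t_test(a, b, variant="pooled") == \
            pytest.approx(expected, abs=1e-10)

    def test_auto_falls_back_to_welch_on_unequal_variances(self):
        rng = np.random.default_rng(23)
        a = rng.normal(0, 0.1, 40)
        b = rng.normal(0.05, 3.0, 40)
        assert independent_t_test(a, b, variant="auto") == \
            pytest.approx(independent_t_test(a, b, variant="welch"))


class TestProportions:
    @pytest.mark.parametrize("k,n,expected", [
        (40, 96, 41.7), (56, 96, 58.3), (0, 96, 0.0), (96, 96, 100.0),
        (1, 8, 12.5),
    ])
    def test_reported_percentages(self, k, n, expected):
        assert proportion_percent(k, n) == expected

    def test_half_up_rounding(self):
        # 5/16 = 31.25 % rounds half-up to 31.3 (not banker's 31.2)
        assert proportion_percent(5, 16) == 31.3

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            proportion_percent(1, 0)
        with pytest.raises(ValueError):
            proportion_percent(5, 3)
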