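"""Statistics battery: exactness, enumeration oracles, closed-form checks."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from allokaryo import (
    anova_two_factor,
    linear_regression,
    rank_sum_one_sided,
    spearman_test,
    t_test_two_sided,
)
from allokaryo.stats import StatResult


class TestStatResult:
    def test_zero_p_rejected(self):
        with pytest.raises(ValueError):
            StatResult(1.0, 0.0, 10, "x")

    def test_p_above_one_rejected(self):
        with pytest.raises(ValueError):
            StatResult(1.0, 1.0001, 10, "x")


class TestRankSum:
    def test_complete_separation_three_vs_three(self):
        # all of a above all of b: only 1 of C(6,3) = 20 labelings is as
        # extreme, so the exact one-sided p is 1/20
        res = rank_sum_one_sided([10, 11, 12], [1, 2, 3], "greater")
        assert res.method == "wilcoxon-rank-sum-exact"
        assert res.p_value == pytest.approx(1 / 20, rel=1e-12)

    def test_wrong_direction_is_high_p(self):
        res = rank_sum_one_sided([1, 2, 3], [10, 11, 12], "greater")
        assert res.p_value == pytest.approx(1.0, rel=1e-12)

    def test_matches_scipy_exact_no_ties(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, int(rng.integers(2, 6)))
            b = rng.normal(0.5, 1, int(rng.integers(2, 6)))
            ours = rank_sum_one_sided(a, b, "greater")
            _, p_ref = scipy.stats.mannwhitneyu(
                a, b, alternative="greater", method="exact"
            )
            assert ours.method == "wilcoxon-rank-sum-exact"
            assert ours.p_value == pytest.approx(p_ref, rel=1e-12)

    def test_tied_values_average_ranked_hand_oracle(self):
        # combined [2,2,1,2]: the three 2s share rank 3; W_a = 6 and 3 of the
        # 6 rank subsets reach it, so p = 0.5
        res = rank_sum_one_sided([2, 2], [1, 2], "greater")
        assert res.p_value == pytest.approx(0.5, rel=1e-12)

    def test_greater_less_duality(self, rng):
        a = rng.normal(0, 1, 4)
        b = rng.normal(0, 1, 5)
        assert rank_sum_one_sided(a, b, "greater").p_value == pytest.approx(
            rank_sum_one_sided(b, a, "less").p_value, rel=1e-12
        )

    def test_unbalanced_large_design_still_exact(self, rng):
        # 100 vs 3 stays enumerable (C(103,3) combinations); complete
        # separation gives exactly 1 / C(103, 3)
        chrom = rng.uniform(25, 35, 100)
        res = rank_sum_one_sided([60.0, 61.0, 62.0], chrom, "greater")
        assert res.method == "wilcoxon-rank-sum-exact"
        assert res.p_value == pytest.approx(1 / math.comb(103, 3), rel=1e-9)

    def test_large_balanced_falls_back_to_normal(self, rng):
        a = rng.normal(0, 1, 40)
        b = rng.normal(0, 1, 40)
        res = rank_sum_one_sided(a, b, "greater")
        assert res.method == "wilcoxon-rank-sum-normal"
        _, p_ref = scipy.stats.mannwhitneyu(
            a, b, alternative="greater", method="asymptotic"
        )
        assert res.p_value == pytest.approx(p_ref, rel=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_one_sided([], [1.0], "greater")


class TestSpearman:
    def test_perfect_monotone_rho_one_exact_p(self):
        # only the identity and full reversal of 5 ranks reach |rho| = 1
        res = spearman_test([1, 2, 3, 4, 5], [2, 4, 8, 16, 32])
        assert res.statistic == pytest.approx(1.0, rel=1e-12)
        assert res.method == "spearman-exact"
        assert res.p_value == pytest.approx(2 / math.factorial(5), rel=1e-12)

    def test_perfect_antitone_rho_minus_one(self):
        res = spearman_test([1, 2, 3, 4], [10, 8, 3, 1])
        assert res.statistic == pytest.approx(-1.0, rel=1e-12)
        assert res.p_value == pytest.approx(2 / math.factorial(4), rel=1e-12)

    def test_matches_full_enumeration_oracle_n6(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        res = spearman_test(x, y)
        rx = scipy.stats.rankdata(x)
        ry = scipy.stats.rankdata(y)
        rho_obs = np.corrcoef(rx, ry)[0, 1]
        count = sum(
            abs(np.corrcoef(rx, perm)[0, 1]) >= abs(rho_obs) - 1e-12
            for perm in itertools.permutations(ry)
        )
        assert res.statistic == pytest.approx(rho_obs, rel=1e-12)
        assert res.p_value == pytest.approx(count / math.factorial(6), rel=1e-12)

    def test_invariant_under_monotone_transforms(self, rng):
        x = rng.uniform(1, 5, 7)
        y = rng.uniform(1, 5, 7)
        base = spearman_test(x, y)
        warped = spearman_test(np.exp(x), y**3)
        assert warped.statistic == pytest.approx(base.statistic, rel=1e-12)
        assert warped.p_value == pytest.approx(base.p_value, rel=1e-12)

    def test_large_n_uses_t_approximation(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        res = spearman_test(x, y)
        assert res.method == "spearman-t-approx"
        rho_ref, p_ref = scipy.stats.spearmanr(x, y)
        assert res.statistic == pytest.approx(rho_ref, rel=1e-12)
        assert res.p_value == pytest.approx(p_ref, rel=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_test([1, 1, 1], [1, 2, 3])


class TestTTest:
    def test_paired_closed_form(self, rng):
        a = rng.normal(1, 0.3, 8)
        b = rng.normal(0.8, 0.3, 8)
        res = t_test_two_sided(a, b, paired=True)
        d = a - b
        t = d.mean() / (d.std(ddof=1) / math.sqrt(d.size))
        p = 2 * scipy.stats.t.sf(abs(t), d.size - 1)
        assert res.df_or_n == 7
        assert res.statistic == pytest.approx(t, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-10)

    def test_welch_closed_form(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(0.5, 2, 14)
        res = t_test_two_sided(a, b)
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        t = (a.mean() - b.mean()) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
        p = 2 * scipy.stats.t.sf(abs(t), df)
        assert res.statistic == pytest.approx(t, rel=1e-10)
        assert res.df_or_n == pytest.approx(df, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-10)

    def test_paired_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            t_test_two_sided([1, 2], [1, 2, 3], paired=True)

    def test_degenerate_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            t_test_two_sided([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])


def balanced_table(mu, effect_m=0.0, effect_c=0.0, interaction=0.0, noise=None, reps=4):
    rows = []
    i = 0
    for m in (0, 1):
        for c in ("hybrid", "parent"):
            for _ in range(reps):
                val = (
                    mu
                    + effect_m * m
                    + effect_c * (c == "hybrid")
                    + interaction * m * (c == "hybrid")
                )
                if noise is not None:
                    val += noise[i]
                    i += 1
                rows.append({"P": val, "M": m, "C": c})
    return pd.DataFrame(rows)


class TestAnova:
    def test_balanced_2x2_hand_sums_of_squares(self, rng):
        noise = rng.normal(0, 1.5, 16)
        tab = balanced_table(50, effect_m=3, effect_c=-2, interaction=1, noise=noise)
        out = anova_two_factor(tab)
        # balanced design: sequential SS equal the textbook marginal formulas
        p = tab["P"].to_numpy()
        grand = p.mean()
        ss_m = sum(
            8 * (p[tab["M"] == m].mean() - grand) ** 2 for m in (0, 1)
        )
        ss_c = sum(
            8 * (p[tab["C"] == c].mean() - grand) ** 2 for c in ("hybrid", "parent")
        )
        cell_means = {
            (m, c): p[(tab["M"] == m) & (tab["C"] == c)].mean()
            for m in (0, 1)
            for c in ("hybrid", "parent")
        }
        ss_cells = sum(4 * (v - grand) ** 2 for v in cell_means.values())
        ss_int = ss_cells - ss_m - ss_c
        ss_res = sum(
            (p[(tab["M"] == m) & (tab["C"] == c)] - cell_means[(m, c)]) ** 2
        for m in (0, 1) for c in ("hybrid", "parent")).sum()
        ms_res = ss_res / 12
        for term, ss, df in (("M", ss_m, 1), ("C", ss_c, 1), ("M:C", ss_int, 1)):
            f = (ss / df) / ms_res
            p_ref = scipy.stats.f.sf(f, df, 12)
            assert out[term].extra["ss"] == pytest.approx(ss, rel=1e-9)
            assert out[term].statistic == pytest.approx(f, rel=1e-9)
            assert out[term].p_value == pytest.approx(p_ref, rel=1e-9)

    def test_pure_effect_detected_with_power(self):
        # effect 3x the noise SD: should essentially always be significant
        hits = 0
        n_sim = 60
        master = np.random.default_rng(7)
        for _ in range(n_sim):
            noise = master.normal(0, 1.0, 16)
            tab = balanced_table(50, effect_m=3.0, noise=noise)
            hits += anova_two_factor(tab)["M"].p_value < 0.05
        assert hits / n_sim > 0.8

    def test_null_type_i_error_controlled(self):
        hits = 0
        n_sim = 300
        master = np.random.default_rng(11)
        for _ in range(n_sim):
            noise = master.normal(0, 1.0, 16)
            tab = balanced_table(50, noise=noise)
            hits += anova_two_factor(tab)["M"].p_value < 0.05
        assert hits / n_sim <= 0.07

    def test_single_level_factor_rejected(self):
        tab = balanced_table(50)
        tab["M"] = 0
        with pytest.raises(ValueError):
            anova_two_factor(tab)

    def test_exact_zero_effect_zero_noise_reports_p_one(self):
        out = anova_two_factor(balanced_table(50.0))
        for term in ("M", "C", "M:C"):
            assert out[term].statistic == 0.0
            assert out[term].p_value == 1.0


class TestLinearRegression:
    def test_slope_intercept_r2_closed_form(self, rng):
        x = rng.uniform(0, 10, 20)
        y = 2.5 * x + 1.0 + rng.normal(0, 1, 20)
        res = linear_regression(x, y)
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        intercept = y.mean() - slope * x.mean()
        r2 = np.corrcoef(x, y)[0, 1] ** 2
        assert res.statistic == pytest.approx(slope, rel=1e-10)
        assert res.extra["intercept"] == pytest.approx(intercept, rel=1e-10)
        assert res.extra["r_squared"] == pytest.approx(r2, rel=1e-10)

    def test_p_matches_t_test_on_slope(self, rng):
        x = rng.uniform(0, 10, 15)
        y = 0.3 * x + rng.normal(0, 1, 15)
        res = linear_regression(x, y)
        n = x.size
        slope = res.statistic
        resid = y - (slope * x + res.extra["intercept"])
        se = math.sqrt(
            (resid @ resid) / (n - 2) / ((x - x.mean()) @ (x - x.mean()))
        )
        p_ref = 2 * scipy.stats.t.sf(abs(slope / se), n - 2)
        assert res.p_value == pytest.approx(p_ref, rel=1e-9)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            linear_regression([1, 1, 1], [1, 2, 3])
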