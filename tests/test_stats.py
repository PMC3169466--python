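"""Trend statistics vs brute-force sums-of-squares and library oracles."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from cprqual import (
    ValidationError,
    ZeroVarianceError,
    bonferroni_alpha,
    nfr_trend_analysis,
    paired_t,
    rm_anova,
)


def brute_force_ss(x):
    """Oracle: within-subject SS decomposition by explicit double loops."""
    n, k = x.shape
    gm = sum(x[i][j] for i in range(n) for j in range(k)) / (n * k)
    row_means = [sum(x[i]) / k for i in range(n)]
    col_means = [sum(x[i][j] for i in range(n)) / n for j in range(k)]
    ss_total = sum((x[i][j] - gm) ** 2 for i in range(n) for j in range(k))
    ss_subj = k * sum((rm - gm) ** 2 for rm in row_means)
    ss_cond = n * sum((cm - gm) ** 2 for cm in col_means)
    return ss_cond, ss_subj, ss_total - ss_cond - ss_subj


class TestBonferroni:
    def test_three_pairwise_tests_level(self):
        alpha = bonferroni_alpha(0.05, 3)
        assert alpha == pytest.approx(0.05 / 3)
        assert round(alpha, 3) == 0.017

    @pytest.mark.parametrize(
        "family,n,expected", [(0.05, 1, 0.05), (0.06, 2, 0.03)]
    )
    def test_arithmetic(self, family, n, expected):
        assert bonferroni_alpha(family, n) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            bonferroni_alpha(0.05, 0)
        with pytest.raises(ValidationError):
            bonferroni_alpha(1.5, 3)


class TestPairedT:
    def test_identical_vectors_null(self):
        res = paired_t(np.ones(5), np.ones(5))
        assert res.t_stat == 0.0
        assert res.p_value == 1.0

    def test_known_value_against_formula_oracle(self):
        # d = (1,2,3,4): mean 2.5, sd sqrt(5/3) -> t = 2.5 / (sd/2) = sqrt(15)
        res = paired_t(np.array([1.0, 2.0, 3.0, 4.0]), np.zeros(4))
        assert res.t_stat == pytest.approx(math.sqrt(15.0), abs=1e-12)
        assert res.df == 3

    def test_matches_scipy_on_random_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a, b = rng.normal(size=(2, 19))
            mine = paired_t(a, b)
            ref = sps.ttest_rel(a, b)
            assert mine.t_stat == pytest.approx(ref.statistic, abs=1e-10)
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_antisymmetric(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=(2, 10))
        fwd, rev = paired_t(a, b), paired_t(b, a)
        assert fwd.t_stat == pytest.approx(-rev.t_stat)
        assert fwd.p_value == pytest.approx(rev.p_value)

    def test_degenerate_constant_difference(self):
        with pytest.raises(ZeroVarianceError):
            paired_t(np.array([1.0, 2.0, 3.0]), np.array([0.0, 1.0, 2.0]))

    def test_too_short(self):
        with pytest.raises(ValidationError):
            paired_t(np.array([1.0]), np.array([2.0]))


class TestRmAnova:
    def test_matches_brute_force_oracle_on_random_matrices(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            x = rng.normal(size=(19, 4))
            res = rm_anova(x)
            ss_cond, ss_subj, ss_err = brute_force_ss(x)
            assert res.ss_conditions == pytest.approx(ss_cond, abs=1e-9)
            assert res.ss_subjects == pytest.approx(ss_subj, abs=1e-9)
            assert res.ss_error == pytest.approx(ss_err, abs=1e-9)
            assert res.df_effect == 3 and res.df_error == 54

    def test_k2_equals_squared_paired_t(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            x = rng.normal(size=(10, 2))
            res = rm_anova(x)
            t = paired_t(x[:, 0], x[:, 1])
            assert res.f_stat == pytest.approx(t.t_stat**2, rel=1e-10)
            assert res.p_value == pytest.approx(t.p_value, rel=1e-10)

    def test_matches_statsmodels_anova_rm(self):
        import pandas as pd
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(13)
        x = rng.normal(size=(19, 4))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(19), 4),
                "cond": np.tile(np.arange(4), 19),
                "y": x.ravel(),
            }
        )
        ref = AnovaRM(long, "y", "subject", within=["cond"]).fit()
        res = rm_anova(x)
        assert res.f_stat == pytest.approx(ref.anova_table["F Value"].iloc[0], rel=1e-9)
        assert res.p_value == pytest.approx(ref.anova_table["Pr > F"].iloc[0], rel=1e-9)

    def test_greenhouse_geisser_correction(self):
        # frozen values cross-checked against an independent implementation
        rng = np.random.default_rng(99)
        x = rng.normal(size=(19, 4)) + np.array([0.0, 0.05, -0.1, 0.02])
        plain = rm_anova(x)
        gg = rm_anova(x, greenhouse_geisser=True)
        assert gg.f_stat == pytest.approx(plain.f_stat)  # F itself unchanged
        assert gg.gg_epsilon == pytest.approx(0.908343, abs=1e-6)
        assert gg.p_value == pytest.approx(0.286641, abs=1e-6)
        assert gg.p_value > plain.p_value  # correction is conservative
        assert plain.gg_epsilon is None
        # epsilon stays within its theoretical bounds on arbitrary data
        y = rng.normal(size=(10, 4)) * np.array([1.0, 5.0, 0.2, 2.0])
        eps = rm_anova(y, greenhouse_geisser=True).gg_epsilon
        assert 1.0 / 3.0 <= eps <= 1.0

    def test_subject_shift_invariance(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=(12, 4))
        shifted = x + rng.normal(size=(12, 1)) * 5.0
        assert rm_anova(shifted).f_stat == pytest.approx(rm_anova(x).f_stat, rel=1e-9)

    def test_pure_subject_effects_give_zero_f(self):
        x = np.repeat(np.arange(1.0, 6.0)[:, None], 4, axis=1)
        res = rm_anova(x)
        assert res.f_stat == 0.0
        assert res.p_value == 1.0

    def test_all_identical_cells_error(self):
        with pytest.raises(ZeroVarianceError):
            rm_anova(np.full((5, 4), 3.0))


class TestTrendAnalysis:
    def test_constant_matrix_errors(self):
        with pytest.raises(ZeroVarianceError):
            nfr_trend_analysis(np.full((19, 4), 0.2))

    def test_shifted_final_period_orders_p_values(self):
        rng = np.random.default_rng(15)
        x = 0.2 + rng.normal(scale=0.01, size=(19, 4))
        x[:, 3] -= 0.1  # large drop in period 4 only
        rep = nfr_trend_analysis(x)
        p12, p13, p14 = (t.p_value for t in rep.pairwise)
        assert p14 < p12 and p14 < p13
        assert rep.pairwise[2].significant_at_bonferroni
        assert not rep.pairwise[0].significant_at_bonferroni
        assert rep.alpha_adjusted == pytest.approx(0.05 / 3)
        assert [t.periods for t in rep.pairwise] == [(1, 2), (1, 3), (1, 4)]

    def test_report_serialises(self):
        rng = np.random.default_rng(16)
        rep = nfr_trend_analysis(rng.normal(size=(19, 4)))
        d = rep.to_dict()
        assert set(d) == {"anova", "pairwise", "alpha_adjusted", "family_alpha"}
        assert len(d["pairwise"]) == 3
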