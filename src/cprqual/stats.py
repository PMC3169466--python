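"""Cohort trend statistics for the windowed no-flow ratio.

The trend over the four three-minute periods is assessed with a one-way
repeated-measures ANOVA (within-subject factor: period), followed by paired
t-tests of period 1 against each later period, Bonferroni-adjusted for the
three comparisons (family alpha 0.05 -> per-test level 0.05/3 ~ 0.017).

The sums of squares are computed from the textbook decomposition rather than
delegated to a modelling package, so they can be verified against an
independent brute-force oracle:

    SS_total = sum_ij (x_ij - grand_mean)^2
    SS_subj  = k * sum_i (row_mean_i - grand_mean)^2
    SS_cond  = n * sum_j (col_mean_j - grand_mean)^2
    SS_err   = SS_total - SS_subj - SS_cond
    F        = (SS_cond / (k-1)) / (SS_err / ((k-1)(n-1)))

No sphericity correction is applied by default; with k = 2 conditions the
F statistic equals the squared paired-t statistic exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import ValidationError, ZeroVarianceError


@dataclass(frozen=True)
class RmAnovaResult:
    """One-way repeated-measures ANOVA result.

    ``df_effect``/``df_error`` are the uncorrected degrees of freedom; when
    Greenhouse-Geisser correction was requested, ``gg_epsilon`` holds the
    sphericity estimate and ``p_value`` comes from the epsilon-scaled
    degrees of freedom.
    """

    f_stat: float
    df_effect: int
    df_error: int
    p_value: float
    ss_conditions: float
    ss_subjects: float
    ss_error: float
    gg_epsilon: float | None = None

    def to_dict(self) -> dict:
        d = {
            "F": self.f_stat,
            "df": [self.df_effect, self.df_error],
            "p": self.p_value,
        }
        if self.gg_epsilon is not None:
            d["gg_epsilon"] = self.gg_epsilon
        return d


@dataclass(frozen=True)
class PairedTestResult:
    """Two-sided paired t-test result with a Bonferroni significance flag."""

    t_stat: float
    df: int
    p_value: float
    significant_at_bonferroni: bool
    periods: tuple[int, int] | None = None

    def to_dict(self) -> dict:
        d = {
            "t": self.t_stat,
            "df": self.df,
            "p": self.p_value,
            "significant": self.significant_at_bonferroni,
        }
        if self.periods is not None:
            d["periods"] = list(self.periods)
        return d


def bonferroni_alpha(family_alpha: float, n_tests: int) -> float:
    """Per-test significance level under Bonferroni correction."""
    if not 0 < family_alpha < 1:
        raise ValidationError(f"family_alpha must be in (0,1), got {family_alpha}")
    if n_tests < 1:
        raise ValidationError(f"n_tests must be >= 1, got {n_tests}")
    return family_alpha / n_tests


def paired_t(
    a: np.ndarray,
    b: np.ndarray,
    alpha: float = 0.05,
    periods: tuple[int, int] | None = None,
) -> PairedTestResult:
    """Two-sided paired t-test of ``a`` vs ``b``.

    ``t = mean(d) / (sd(d)/sqrt(n))`` with ``d = a - b`` and the n-1
    denominator in the sample standard deviation.  Identical vectors give
    t = 0, p = 1; a constant nonzero difference has no sampling variance and
    raises :class:`ZeroVarianceError`.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError(f"paired vectors must be 1-d and equal length")
    n = a.size
    if n < 2:
        raise ValidationError(f"paired t-test needs n >= 2, got {n}")
    d = a - b
    sd = float(np.std(d, ddof=1))
    mean = float(np.mean(d))
    if sd == 0.0:
        if mean == 0.0:
            return PairedTestResult(
                t_stat=0.0, df=n - 1, p_value=1.0,
                significant_at_bonferroni=False, periods=periods,
            )
        raise ZeroVarianceError(
            "paired differences are a nonzero constant; t is undefined"
        )
    t = mean / (sd / np.sqrt(n))
    p = float(2.0 * sps.t.sf(abs(t), df=n - 1))
    return PairedTestResult(
        t_stat=float(t),
        df=n - 1,
        p_value=p,
        significant_at_bonferroni=p < alpha,
        periods=periods,
    )


def _gg_epsilon(x: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity estimate from the condition covariances.

    ``eps = trace(S*)^2 / ((k-1) * sum(S*^2))`` with S* the double-centred
    sample covariance matrix of the k conditions; bounded to [1/(k-1), 1].
    """
    n, k = x.shape
    s = np.cov(x, rowvar=False, ddof=1)
    h = np.eye(k) - np.full((k, k), 1.0 / k)
    s_dc = h @ s @ h
    denom = (k - 1) * float((s_dc**2).sum())
    if denom == 0.0:
        return 1.0
    eps = float(np.trace(s_dc)) ** 2 / denom
    return float(min(1.0, max(eps, 1.0 / (k - 1))))


def rm_anova(matrix: np.ndarray, greenhouse_geisser: bool = False) -> RmAnovaResult:
    """One-way repeated-measures ANOVA on an n-subjects x k-conditions matrix.

    With ``greenhouse_geisser`` the p-value is computed from
    epsilon-scaled degrees of freedom (off by default: the plain test is
    the reference analysis; the correction guards against sphericity
    violations at some power cost).

    Raises :class:`ZeroVarianceError` when every cell is identical, or when
    the error sum of squares vanishes while a condition effect exists (F is
    then unbounded).  Pure subject shifts (each subject constant across
    conditions) give F = 0, p = 1: there is no condition effect to test.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValidationError("matrix must be 2-d (subjects x conditions)")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValidationError(f"need >= 2 subjects and >= 2 conditions, got {n}x{k}")
    gm = x.mean()
    ss_total = float(((x - gm) ** 2).sum())
    if ss_total == 0.0:
        raise ZeroVarianceError("all cells identical; ANOVA undefined")
    ss_subj = float(k * ((x.mean(axis=1) - gm) ** 2).sum())
    ss_cond = float(n * ((x.mean(axis=0) - gm) ** 2).sum())
    ss_err = ss_total - ss_subj - ss_cond
    df_effect = k - 1
    df_error = (k - 1) * (n - 1)
    eps: float | None = None
    if ss_cond == 0.0:
        f = 0.0
        p = 1.0
        if greenhouse_geisser:
            eps = _gg_epsilon(x)
    elif ss_err <= 0.0:
        raise ZeroVarianceError(
            "error sum of squares is zero; F statistic is unbounded"
        )
    else:
        f = (ss_cond / df_effect) / (ss_err / df_error)
        if greenhouse_geisser:
            eps = _gg_epsilon(x)
            p = float(sps.f.sf(f, eps * df_effect, eps * df_error))
        else:
            p = float(sps.f.sf(f, df_effect, df_error))
    return RmAnovaResult(
        f_stat=float(f),
        df_effect=df_effect,
        df_error=df_error,
        p_value=p,
        ss_conditions=ss_cond,
        ss_subjects=ss_subj,
        ss_error=max(ss_err, 0.0),
        gg_epsilon=eps,
    )


@dataclass(frozen=True)
class TrendReport:
    """Combined NFR trend analysis: omnibus ANOVA plus pairwise tests."""

    anova: RmAnovaResult
    pairwise: tuple[PairedTestResult, ...]
    alpha_adjusted: float
    family_alpha: float = 0.05

    def to_dict(self) -> dict:
        return {
            "anova": self.anova.to_dict(),
            "pairwise": [t.to_dict() for t in self.pairwise],
            "alpha_adjusted": self.alpha_adjusted,
            "family_alpha": self.family_alpha,
        }


def nfr_trend_analysis(
    matrix: np.ndarray,
    family_alpha: float = 0.05,
    greenhouse_geisser: bool = False,
) -> TrendReport:
    """Trend statistics on an attempts x 4-window NFR matrix.

    Runs the omnibus repeated-measures ANOVA and the three paired t-tests of
    window 1 against windows 2, 3 and 4, each flagged against the
    Bonferroni-adjusted level ``family_alpha / 3``.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] != 4:
        raise ValidationError("NFR matrix must be attempts x 4 windows")
    anova = rm_anova(x, greenhouse_geisser=greenhouse_geisser)
    n_tests = x.shape[1] - 1
    alpha_adj = bonferroni_alpha(family_alpha, n_tests)
    pairwise = tuple(
        paired_t(x[:, 0], x[:, j], alpha=alpha_adj, periods=(1, j + 1))
        for j in range(1, x.shape[1])
    )
    return TrendReport(
        anova=anova,
        pairwise=pairwise,
        alpha_adjusted=alpha_adj,
        family_alpha=family_alpha,
    )
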