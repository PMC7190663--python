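"""Statistics battery: rank tests, t-tests, two-factor ANOVA, regression.

Small-sample nonparametric tests use exact null distributions computed by
enumeration (with average-rank tie handling); larger samples fall back to
the standard normal/t approximations with continuity and tie corrections.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

EXACT_RANKSUM_MAX_N = 12
EXACT_RANKSUM_MAX_COMB = 200_000  # unbalanced designs stay enumerable
EXACT_SPEARMAN_MAX_N = 8

__all__ = [
    "StatResult",
    "rank_sum_one_sided",
    "spearman_test",
    "t_test_two_sided",
    "anova_two_factor",
    "linear_regression",
]


@dataclass
class StatResult:
    statistic: float
    p_value: float
    df_or_n: float
    method: str
    extra: dict | None = None

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1):
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")


def _exact_ranksum_p(a: np.ndarray, b: np.ndarray, alternative: str) -> float:
    """Exact one-sided rank-sum p by enumerating all assignments of the
    combined (average-tie) ranks to the smaller group."""
    combined = np.concatenate([a, b])
    ranks = scipy.stats.rankdata(combined)
    n, na = len(combined), len(a)
    if na <= n - na:
        w_obs = ranks[:na].sum()
        size, flip = na, False
    else:
        # enumerate the smaller (second) group; W_a = total - W_b, so the
        # tail probability flips direction
        w_obs = ranks[na:].sum()
        size, flip = n - na, True
    want_greater = (alternative == "greater") != flip
    count = 0
    total = 0
    for idx in itertools.combinations(range(n), size):
        w = ranks[list(idx)].sum()
        total += 1
        if want_greater:
            count += w >= w_obs - 1e-9
        else:
            count += w <= w_obs + 1e-9
    return count / total


def rank_sum_one_sided(a, b, alternative: str = "greater") -> StatResult:
    """One-sided Wilcoxon rank-sum (Mann-Whitney) test of ``a`` against ``b``.

    ``alternative='greater'`` tests whether values in ``a`` tend to exceed
    those in ``b``.  Exact enumeration when the combined sample size is at
    most 12; normal approximation with continuity and tie correction
    otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in {"greater", "less"}:
        raise ValueError("alternative must be 'greater' or 'less'")
    u, _ = scipy.stats.mannwhitneyu(a, b, alternative=alternative)
    n = a.size + b.size
    n_comb = math.comb(n, min(a.size, b.size))
    if n <= EXACT_RANKSUM_MAX_N or n_comb <= EXACT_RANKSUM_MAX_COMB:
        p = _exact_ranksum_p(a, b, alternative)
        method = "wilcoxon-rank-sum-exact"
    else:
        _, p = scipy.stats.mannwhitneyu(
            a, b, alternative=alternative, method="asymptotic"
        )
        method = "wilcoxon-rank-sum-normal"
    return StatResult(float(u), float(p), n, method)


def _spearman_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


def spearman_test(x, y) -> StatResult:
    """Spearman rank correlation with two-sided p-value.

    Ties are average-ranked.  For n <= 8 the p-value is exact over all n!
    permutations of one vector; otherwise the usual t-approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman rho undefined for a constant vector")
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    rho = _spearman_rho(rx, ry)
    n = x.size
    if n <= EXACT_SPEARMAN_MAX_N:
        target = abs(rho) - 1e-12
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            total += 1
            if abs(_spearman_rho(rx, np.array(perm))) >= target:
                count += 1
        p = count / total
        method = "spearman-exact"
    else:
        _, p = scipy.stats.spearmanr(x, y)
        method = "spearman-t-approx"
    return StatResult(rho, float(min(p, 1.0)), n, method)


def t_test_two_sided(a, b, paired: bool = False) -> StatResult:
    """Two-sided t-test: paired (df = n-1) or unpaired Welch (Welch df)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if a.size != b.size:
            raise ValueError("paired test requires equal lengths")
        if a.size < 2:
            raise ValueError("need at least 2 pairs")
        d = a - b
        if np.allclose(d.var(ddof=1), 0) and np.allclose(d.mean(), 0):
            raise ValueError("zero variance and zero difference: t undefined")
        res = scipy.stats.ttest_rel(a, b)
        df = a.size - 1
        method = "t-test-paired"
    else:
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            if a.mean() == b.mean():
                raise ValueError("zero variance in both samples: t undefined")
        res = scipy.stats.ttest_ind(a, b, equal_var=False)
        df = float(res.df)
        method = "t-test-welch"
    return StatResult(float(res.statistic), float(res.pvalue), df, method)


def anova_two_factor(table: pd.DataFrame) -> dict[str, StatResult]:
    """Multifactor ANOVA of retention percent against mtDNA donor and strain
    class: P ~ M * C with sequential (type-I) sums of squares.

    ``table`` needs columns ``P`` (response, percent), ``M`` (mtDNA donor,
    binary) and ``C`` (strain class label).  Returns one StatResult per term
    (``M``, ``C``, ``M:C``); F == 0 is reported with p = 1.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame(
        {"resp": table["P"], "mfac": table["M"].astype(str), "cfac": table["C"].astype(str)}
    )
    for col, label in (("mfac", "M"), ("cfac", "C")):
        if df[col].nunique() < 2:
            raise ValueError(f"factor {label} needs at least 2 levels")
    if df["resp"].nunique() == 1:
        # constant response: every effect is exactly zero
        dfm = df["mfac"].nunique() - 1
        dfc = df["cfac"].nunique() - 1
        return {
            term: StatResult(0.0, 1.0, float(d), "anova-type1", extra={"ss": 0.0})
            for term, d in (("M", dfm), ("C", dfc), ("M:C", dfm * dfc))
        }
    model = smf.ols("resp ~ C(mfac) * C(cfac)", data=df).fit()
    if model.df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    tab = sm.stats.anova_lm(model, typ=1)
    rename = {"C(mfac)": "M", "C(cfac)": "C", "C(mfac):C(cfac)": "M:C"}
    out: dict[str, StatResult] = {}
    for row_name, term in rename.items():
        if row_name not in tab.index:
            continue
        row = tab.loc[row_name]
        if row["df"] < 1:
            raise ValueError(f"term {term} has 0 degrees of freedom (confounded design)")
        f = float(row["F"])
        p = float(row["PR(>F)"])
        if not np.isfinite(f):  # zero residual SS with zero effect SS
            f, p = 0.0, 1.0
        out[term] = StatResult(f, min(max(p, np.nextafter(0, 1)), 1.0), float(row["df"]),
                               "anova-type1", extra={"ss": float(row["sum_sq"])})
    return out


def linear_regression(x, y) -> StatResult:
    """Ordinary least-squares line fit; returns the slope as statistic with
    the F-test p-value, and r², intercept in ``extra``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("constant x: regression undefined")
    res = scipy.stats.linregress(x, y)
    p = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
    return StatResult(
        float(res.slope),
        min(max(p, np.nextafter(0, 1)), 1.0),
        x.size,
        "linear-regression",
        extra={"r_squared": float(res.rvalue**2), "intercept": float(res.intercept)},
    )
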