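"""The study's statistical battery.

Per-group summaries with t-based 95 % confidence intervals, two-observer
ICC(2,1) (two-way random effects, absolute agreement, single measures),
Tamhane's T2 all-pairs comparisons (Welch t statistics with
Welch-Satterthwaite degrees of freedom and a Sidak-type adjustment over
the number of pairs), independent-samples t-tests (pooled with an
automatic Welch fallback when an F-test rejects equal variances, emulating
common SPSS practice), and half-up percentage rounding for reported
proportions.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "PairwiseResult",
    "InsufficientDataError",
    "summarize_group",
    "icc_two_observers",
    "tamhane_t2",
    "welch_t",
    "independent_t_test",
    "proportion_percent",
]


class InsufficientDataError(ValueError):
    """Too few observations for the requested statistic."""


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class PairwiseResult:
    group_i: int
    group_j: int
    t_stat: float
    welch_df: float
    p_raw: float
    p_adjusted: float


def summarize_group(values, label: str = "") -> GroupSummary:
    """Mean, sample SD and t-based 95 % CI of one group of ratios."""
    x = np.asarray(values, float)
    n = len(x)
    if n < 2:
        raise InsufficientDataError(f"need n >= 2 for a CI, got n={n}")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    half = float(sps.t.ppf(0.975, n - 1)) * sd / np.sqrt(n)
    return GroupSummary(label=label, n=n, mean=mean, sd=sd,
                        ci_low=mean - half, ci_high=mean + half)


def icc_two_observers(obs1, obs2) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    Computed from the two-way ANOVA decomposition with k = 2 raters:
    ``(MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)``.
    """
    x = np.asarray(obs1, float)
    y = np.asarray(obs2, float)
    if x.shape != y.shape:
        raise ParameterMismatch("observer vectors must have equal length")
    n = len(x)
    if n < 3:
        raise InsufficientDataError(f"need n >= 3 subjects, got n={n}")
    data = np.stack([x, y], axis=1)          # (n subjects, k=2 raters)
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((data - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if abs(denom) < 1e-30:
        return 1.0 if abs(msr - mse) < 1e-30 else float("nan")
    return float((msr - mse) / denom)


class ParameterMismatch(ValueError):
    pass


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch t statistic, Welch-Satterthwaite df and two-sided p."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("each group needs n >= 2")
    v1 = a.var(ddof=1) / n1
    v2 = b.var(ddof=1) / n2
    se2 = v1 + v2
    if se2 <= 0:
        t = 0.0
        df = float(n1 + n2 - 2)
    else:
        t = float((a.mean() - b.mean()) / np.sqrt(se2))
        df = float(se2 ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1)))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return t, df, min(p, 1.0)


def tamhane_t2(groups) -> list[PairwiseResult]:
    """Tamhane's T2: all-pairs Welch t tests with a Sidak-type adjustment.

    With m pairs, ``p_adj = 1 - (1 - p)^m`` clamped to [0, 1] -- the
    conservative multiplicative inequality that defines T2.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2:
        raise InsufficientDataError("need at least 2 groups")
    for g in groups:
        if len(g) < 2:
            raise InsufficientDataError("every group needs n >= 2")
    m = len(groups) * (len(groups) - 1) // 2
    out = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            t, df, p = welch_t(groups[i], groups[j])
            # 1 - (1-p)^m, computed stably for tiny p
            p_adj = float(-np.expm1(m * np.log1p(-min(p, 1.0 - 1e-16))))
            p_adj = min(max(p_adj, 0.0), 1.0)
            if p >= 1.0:
                p_adj = 1.0
            out.append(PairwiseResult(i, j, t, df, p, p_adj))
    return out


def independent_t_test(group_a, group_b, variant: str = "auto") -> float:
    """Two-sided independent-samples t-test p-value.

    ``variant``: "pooled", "welch", or "auto" (pooled unless a two-sided
    F-test of variances rejects at 0.05, then Welch -- the usual SPSS
    reading workflow).
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each group needs n >= 2")
    if variant not in ("auto", "pooled", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    use_welch = variant == "welch"
    if variant == "auto":
        v1, v2 = a.var(ddof=1), b.var(ddof=1)
        if v1 > 0 and v2 > 0:
            f = v1 / v2
            p_f = 2.0 * min(sps.f.cdf(f, len(a) - 1, len(b) - 1),
                            sps.f.sf(f, len(a) - 1, len(b) - 1))
            use_welch = p_f < 0.05
    if use_welch:
        return welch_t(a, b)[2]
    n1, n2 = len(a), len(b)
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 <= 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return float(min(2.0 * sps.t.sf(abs(t), n1 + n2 - 2), 1.0))


def proportion_percent(k: int, n: int) -> float:
    """100*k/n, rounded half-up to one decimal (as reported percentages)."""
    if n <= 0:
        raise ValueError(f"n must be > 0, got {n}")
    if not 0 <= k <= n:
        raise ValueError(f"k must lie in [0, n], got k={k}, n={n}")
    value = Decimal(100 * k) / Decimal(n)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
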