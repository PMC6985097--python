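"""Group statistics and significance reporting.

Measurements are summarized as mean +/- SEM.  Omnibus differences across
timepoints or treatments are tested by one-way ANOVA with Bonferroni-adjusted
pairwise comparisons (pooled-variance t statistics on the ANOVA residual
variance, the convention of standard post-hoc software), or by the two-sided
Mann-Whitney rank-sum test where the ANOVA assumptions are doubtful.
Significance stars follow the usual convention: * p < 0.05, ** p < 0.01,
*** p < 0.001.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "mean_sem",
    "significance_stars",
    "anova_bonferroni",
    "mann_whitney",
    "choose_test",
    "compare_groups",
]


def mean_sem(values: Sequence[float]) -> tuple[float, Optional[float], int]:
    """Mean, standard error of the mean (sample SD / sqrt(n)), and n.

    SEM is ``None`` for a single observation (undefined sample SD).
    """
    a = np.asarray(list(values), dtype=float)
    if a.size == 0:
        raise ValueError("mean_sem of an empty sequence")
    if not np.all(np.isfinite(a)):
        raise ValueError("values must be finite")
    n = int(a.size)
    mean = float(a.mean())
    if n == 1:
        return mean, None, n
    sem = float(a.std(ddof=1) / math.sqrt(n))
    return mean, sem, n


def significance_stars(p: float) -> str:
    """'*' for p<0.05, '**' for p<0.01, '***' for p<0.001, else 'ns'."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class ComparisonResult:
    """Outcome of an omnibus test plus adjusted pairwise comparisons."""

    test_name: str
    statistic: float
    p_value: float
    pairwise: list[dict] = field(default_factory=list)
    stars: str = "ns"
    flags: list[str] = field(default_factory=list)


def anova_bonferroni(groups: Mapping[str, Sequence[float]]) -> ComparisonResult:
    """One-way ANOVA with Bonferroni-adjusted pairwise comparisons.

    Pairwise t statistics use the pooled residual variance from the ANOVA
    (df = N - k); raw p-values are multiplied by the number of pairs and
    capped at 1.  Each group needs at least 2 observations.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    arrays: dict[str, np.ndarray] = {}
    for name, vals in groups.items():
        a = np.asarray(list(vals), dtype=float)
        if a.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
        arrays[name] = a
    f_stat, p_omni = sps.f_oneway(*arrays.values())
    names = list(arrays)
    n_total = sum(a.size for a in arrays.values())
    k = len(arrays)
    df_resid = n_total - k
    mse = sum(
        float(((a - a.mean()) ** 2).sum()) for a in arrays.values()
    ) / df_resid
    pairs = list(combinations(names, 2))
    n_pairs = len(pairs)
    pairwise = []
    for a_name, b_name in pairs:
        a, b = arrays[a_name], arrays[b_name]
        se = math.sqrt(mse * (1.0 / a.size + 1.0 / b.size))
        t = (a.mean() - b.mean()) / se if se > 0 else 0.0
        p_raw = float(2.0 * sps.t.sf(abs(t), df_resid)) if se > 0 else 1.0
        p_adj = min(1.0, p_raw * n_pairs)
        pairwise.append(
            {
                "group_a": a_name,
                "group_b": b_name,
                "statistic": float(t),
                "p_raw": p_raw,
                "p_adjusted": p_adj,
                "stars": significance_stars(p_adj),
            }
        )
    return ComparisonResult(
        test_name="anova+bonferroni",
        statistic=float(f_stat),
        p_value=float(p_omni),
        pairwise=pairwise,
        stars=significance_stars(float(p_omni)),
    )


def mann_whitney(
    group_a: Sequence[float], group_b: Sequence[float], *, exact_max_n: int = 8
) -> ComparisonResult:
    """Two-sided Mann-Whitney rank-sum test.

    Uses the exact null distribution when both samples have at most
    ``exact_max_n`` observations and no ties are present, the tie-corrected
    normal approximation otherwise.  If every value across both groups is
    identical the comparison is uninformative: p = 1, flagged.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both groups need at least 1 observation")
    flags: list[str] = []
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return ComparisonResult(
            test_name="mann-whitney",
            statistic=float(a.size * b.size / 2.0),
            p_value=1.0,
            stars="ns",
            flags=["all values tied"],
        )
    has_ties = np.unique(pooled).size < pooled.size
    if a.size <= exact_max_n and b.size <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
        if has_ties:
            flags.append("ties: normal approximation with tie correction")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return ComparisonResult(
        test_name=f"mann-whitney ({method})",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        stars=significance_stars(float(res.pvalue)),
        flags=flags,
    )


def choose_test(groups: Mapping[str, Sequence[float]], *, alpha_normality: float = 0.05) -> str:
    """Decide between ANOVA and Mann-Whitney for a set of groups.

    ANOVA is used for >= 3 groups when every group has n >= 5 and passes a
    Shapiro-Wilk normality screen at ``alpha_normality``; otherwise the
    rank-based Mann-Whitney (applied pairwise) is preferred.
    """
    arrays = [np.asarray(list(v), dtype=float) for v in groups.values()]
    if len(arrays) < 3:
        return "mann-whitney"
    for a in arrays:
        if a.size < 5:
            return "mann-whitney"
        if np.ptp(a) == 0:
            return "mann-whitney"
        if sps.shapiro(a).pvalue < alpha_normality:
            return "mann-whitney"
    return "anova"


def compare_groups(groups: Mapping[str, Sequence[float]]) -> ComparisonResult:
    """Apply the test selected by :func:`choose_test`; the choice is recorded.

    With exactly two groups, or when the normality screen fails, pairwise
    Mann-Whitney tests are run; the omnibus p reported is the smallest
    Bonferroni-adjusted pairwise p.
    """
    method = choose_test(groups)
    if method == "anova":
        res = anova_bonferroni(groups)
        res.flags.append("test selected: anova (normality screen passed)")
        return res
    names = list(groups)
    pairs = list(combinations(names, 2))
    pairwise = []
    for a_name, b_name in pairs:
        mw = mann_whitney(groups[a_name], groups[b_name])
        p_adj = min(1.0, mw.p_value * len(pairs))
        pairwise.append(
            {
                "group_a": a_name,
                "group_b": b_name,
                "statistic": mw.statistic,
                "p_raw": mw.p_value,
                "p_adjusted": p_adj,
                "stars": significance_stars(p_adj),
            }
        )
    p_min = min((pw["p_adjusted"] for pw in pairwise), default=1.0)
    return ComparisonResult(
        test_name="mann-whitney (pairwise, bonferroni)",
        statistic=float("nan"),
        p_value=float(p_min),
        pairwise=pairwise,
        stars=significance_stars(float(p_min)),
        flags=["test selected: mann-whitney"],
    )
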