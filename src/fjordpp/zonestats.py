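"""Zone-wise summaries, between-fjord fold-ratios, and the
normality -> variance-homogeneity -> ANOVA / Kruskal-Wallis decision rule.

The comparison procedure mirrors standard practice for fjord-zone data:
Shapiro-Wilk normality per group and Levene's test across groups gate a
one-way ANOVA; if any gate fails, the Kruskal-Wallis rank test is used as
the non-parametric alternative.  Gates and main test share one alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["ZoneSummary", "FoldRatio", "ComparisonResult",
           "summarize_zone", "fold_ratio", "compare_zones"]


class ZoneStatsError(ValueError):
    pass


@dataclass(frozen=True)
class ZoneSummary:
    fjord: str
    zone: str
    variable: str
    n: int
    min: float
    max: float
    mean: float
    sd: float
    single_value: bool = False  # n == 1: sd reported as 0 by convention


@dataclass(frozen=True)
class FoldRatio:
    variable: str
    zone: str
    numerator_fjord: str
    denominator_fjord: str
    ratio: float
    rounding: str


@dataclass(frozen=True)
class ComparisonResult:
    test_used: str                 # "ANOVA" or "KruskalWallis"
    normality_p: tuple[float, ...]
    variance_homogeneity_p: float
    statistic: float
    p_value: float
    alpha: float


def summarize_zone(values: Sequence[float], fjord: str, zone: str,
                   variable: str) -> ZoneSummary:
    """Min-max range, arithmetic mean and sample SD (n-1) of one variable."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ZoneStatsError("empty value list")
    single = arr.size == 1
    return ZoneSummary(
        fjord=fjord, zone=zone, variable=variable, n=int(arr.size),
        min=float(arr.min()), max=float(arr.max()), mean=float(arr.mean()),
        sd=0.0 if single else float(arr.std(ddof=1)), single_value=single,
    )


def _round_ratio(x: float, rounding: str) -> float:
    if rounding == "one_decimal":
        return round(x, 1)
    if rounding == "nearest_half":
        return round(x * 2.0) / 2.0
    raise ZoneStatsError(f"unknown rounding rule {rounding!r}")


def fold_ratio(summary_a: ZoneSummary, summary_b: ZoneSummary,
               rounding: str = "one_decimal") -> FoldRatio:
    """How many times higher the mean of one fjord's zone is than the other's.

    Surface-production ratios are conventionally printed to one decimal;
    integrated-production ratios to the nearest 0.5.
    """
    if summary_a.variable != summary_b.variable or summary_a.zone != summary_b.zone:
        raise ZoneStatsError("fold ratio requires matching variable and zone")
    if summary_b.mean <= 0:
        raise ZoneStatsError("denominator mean must be positive")
    return FoldRatio(
        variable=summary_a.variable, zone=summary_a.zone,
        numerator_fjord=summary_a.fjord, denominator_fjord=summary_b.fjord,
        ratio=_round_ratio(summary_a.mean / summary_b.mean, rounding),
        rounding=rounding,
    )


def compare_zones(groups: Sequence[Sequence[float]], alpha: float = 0.05
                  ) -> ComparisonResult:
    """Gate-then-test comparison of >= 2 groups.

    One-way ANOVA when every group passes Shapiro-Wilk normality and
    Levene's test finds homogeneous variances (all gate p > alpha);
    Kruskal-Wallis otherwise.
    """
    if len(groups) < 2:
        raise ZoneStatsError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrays):
        if g.size < 3:
            raise ZoneStatsError(f"group {i} too small for the decision procedure (n={g.size})")
    norm_p = tuple(float(stats.shapiro(g).pvalue) for g in arrays)
    lev_p = float(stats.levene(*arrays).pvalue)
    if all(p > alpha for p in norm_p) and lev_p > alpha:
        res = stats.f_oneway(*arrays)
        used = "ANOVA"
    else:
        res = stats.kruskal(*arrays)
        used = "KruskalWallis"
    return ComparisonResult(
        test_used=used, normality_p=norm_p, variance_homogeneity_p=lev_p,
        statistic=float(res.statistic), p_value=float(res.pvalue), alpha=alpha,
    )
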