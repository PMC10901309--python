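"""Cohort statistics: normality screening, rank correlation with Fisher-z
confidence intervals, and shows/no-shows group comparisons.

The correlation surface mirrors the analysis this pipeline feeds: Spearman
rank correlation between each per-video mean limb-to-midline distance
(dlm15/16/27/28) and each MTM occurrence metric (occurrence percentage and
the lower/upper/total per-minute rates), with 95% confidence intervals from
the Fisher z-transformation, tanh(atanh(r) +/- z_{1-a/2} / sqrt(n - 3)).

Group comparisons contrast videos that show MTM in a category (Total, Lower,
Upper) against those that do not, on the three normalized area measures:
Student's t for the whole-body quadrilateral area (the one measure that
screens as normal), Mann-Whitney U for the upper and lower triangle areas.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .errors import (
    DegenerateSampleError,
    InsufficientDataError,
    UndefinedCorrelationError,
)
from .geometry import VideoFeatureSummary
from .scoring import MtmScore

DISTANCE_FEATURES = ("mean_dlm15", "mean_dlm16", "mean_dlm27", "mean_dlm28")
MTM_METRICS = ("occurrence_percentage", "rate_lower", "rate_upper", "rate_total")
AREA_MEASURES = ("whole", "upper", "lower")


@dataclasses.dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    ci_low: float
    ci_high: float
    n: int

    @property
    def significant(self) -> bool:
        """Starred at the p < 0.01 level."""
        return self.p < 0.01


@dataclasses.dataclass(frozen=True)
class GroupComparison:
    category: str  # Total | Lower | Upper
    measure: str  # whole | upper | lower
    test: str  # t_test | mann_whitney
    statistic: float
    p: float
    n_show: int
    n_noshow: int
    location_show: float  # mean for t_test, median for mann_whitney
    location_noshow: float


def ks_normality(
    sample: Sequence[float], method: str = "lilliefors"
) -> tuple[float, float]:
    """One-sample KS goodness-of-fit against a normal with plugged-in moments.

    The statistic is sup |ECDF - Phi((x - mean)/sd)| with the sample mean and
    (ddof=1) SD. ``method="lilliefors"`` corrects the p-value for the
    estimated parameters; ``method="ks"`` treats them as fixed (the classical
    Kolmogorov distribution p, anti-conservative under estimation).
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise InsufficientDataError("ks_normality needs n >= 3")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateSampleError("constant sample has no normality test")
    if method == "lilliefors":
        from statsmodels.stats.diagnostic import lilliefors

        stat, p = lilliefors(x, dist="norm", pvalmethod="table")
        return float(stat), float(p)
    if method == "ks":
        res = sps.kstest(x, "norm", args=(x.mean(), sd))
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown method {method!r}")


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks for ties.

    p is two-sided from the t-approximation with n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise InsufficientDataError("spearman needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("constant vector: correlation undefined")
    r, p = sps.spearmanr(x, y)
    return float(r), float(p)


def fisher_ci(
    r: float, n: int, alpha: float = 0.05
) -> tuple[float, float]:
    """Fisher-z confidence interval for a correlation coefficient.

    tanh(atanh(r) +/- z_{1-alpha/2} / sqrt(n - 3)).
    """
    if not -1.0 < r < 1.0:
        raise ValueError("r must lie strictly inside (-1, 1)")
    if n < 4:
        raise InsufficientDataError("fisher_ci needs n >= 4")
    z = math.atanh(r)
    half = sps.norm.ppf(1.0 - alpha / 2.0) / math.sqrt(n - 3)
    return math.tanh(z - half), math.tanh(z + half)


def mann_whitney(
    a: Sequence[float], b: Sequence[float], method: str = "auto"
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; U is the statistic of the first sample.

    ``auto`` enumerates the exact null when min(n) <= 8 and there are no
    ties, otherwise uses the tie-corrected normal approximation with
    continuity correction. With a all greater than b, U = n_a * n_b.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("mann_whitney needs both samples nonempty")
    if method == "auto":
        no_ties = np.unique(np.concatenate([a, b])).size == a.size + b.size
        method = "exact" if (min(a.size, b.size) <= 8 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def independent_t(
    a: Sequence[float], b: Sequence[float], equal_var: bool = True
) -> tuple[float, float]:
    """Two-sample t-test, Student pooled-variance by default (Welch optional)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("independent_t needs n >= 2 per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise DegenerateSampleError("zero variance in both groups")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def _match(
    features: Sequence[VideoFeatureSummary], scores: Sequence[MtmScore]
) -> list[tuple[VideoFeatureSummary, MtmScore]]:
    by_id = {s.video_id: s for s in scores}
    matched = [(f, by_id[f.video_id]) for f in features if f.video_id in by_id]
    return matched


def run_table2(
    features: Sequence[VideoFeatureSummary],
    scores: Sequence[MtmScore],
    alpha: float = 0.05,
) -> dict[tuple[str, str], CorrelationResult]:
    """Spearman r with Fisher-z CI for every distance-feature x MTM-metric cell.

    Keys are (feature, metric) over dlm15/16/27/28 and occurrence percentage
    plus the three per-minute rates. Requires at least 4 matched videos.
    """
    matched = _match(features, scores)
    n = len(matched)
    if n < 4:
        raise InsufficientDataError(f"need >= 4 matched videos, have {n}")
    out: dict[tuple[str, str], CorrelationResult] = {}
    for feat in DISTANCE_FEATURES:
        x = [getattr(f, feat) for f, _ in matched]
        for metric in MTM_METRICS:
            y = [getattr(s, metric) for _, s in matched]
            try:
                r, p = spearman(x, y)
            except UndefinedCorrelationError:
                # a constant column (e.g. no video shows lower-limb MTM)
                # yields an undefined cell, not a failed table
                out[(feat, metric)] = CorrelationResult(
                    r=float("nan"), p=float("nan"),
                    ci_low=float("nan"), ci_high=float("nan"), n=n,
                )
                continue
            if abs(r) == 1.0:  # Fisher z diverges at |r| = 1
                lo = hi = r
            else:
                lo, hi = fisher_ci(r, n, alpha=alpha)
            out[(feat, metric)] = CorrelationResult(r=r, p=p, ci_low=lo, ci_high=hi, n=n)
    return out


def run_group_comparisons(
    features: Sequence[VideoFeatureSummary],
    scores: Sequence[MtmScore],
) -> list[GroupComparison]:
    """Shows vs no-shows area comparisons for each MTM category.

    Whole area: Student's t; upper and lower areas: Mann-Whitney U. A
    category with an empty side is skipped with a warning.
    """
    matched = _match(features, scores)
    if not matched:
        raise InsufficientDataError("no matched videos")
    results: list[GroupComparison] = []
    flags = {
        "Total": lambda s: s.shows_total,
        "Lower": lambda s: s.shows_lower,
        "Upper": lambda s: s.shows_upper,
    }
    measures = {
        "whole": "mean_area_whole",
        "upper": "mean_area_upper",
        "lower": "mean_area_lower",
    }
    for category, flag in flags.items():
        show = [f for f, s in matched if flag(s)]
        noshow = [f for f, s in matched if not flag(s)]
        if not show or not noshow:
            warnings.warn(
                f"category {category}: one group empty "
                f"({len(show)} shows / {len(noshow)} no-shows); skipped",
                stacklevel=2,
            )
            continue
        for measure, attr in measures.items():
            a = np.array([getattr(f, attr) for f in show])
            b = np.array([getattr(f, attr) for f in noshow])
            if measure == "whole":
                if min(a.size, b.size) < 2:
                    warnings.warn(
                        f"category {category}, whole area: a group has fewer "
                        "than 2 videos; t-test skipped",
                        stacklevel=2,
                    )
                    continue
                stat, p = independent_t(a, b)
                results.append(
                    GroupComparison(
                        category=category,
                        measure=measure,
                        test="t_test",
                        statistic=stat,
                        p=p,
                        n_show=a.size,
                        n_noshow=b.size,
                        location_show=float(a.mean()),
                        location_noshow=float(b.mean()),
                    )
                )
            else:
                stat, p = mann_whitney(a, b, method="asymptotic")
                results.append(
                    GroupComparison(
                        category=category,
                        measure=measure,
                        test="mann_whitney",
                        statistic=stat,
                        p=p,
                        n_show=a.size,
                        n_noshow=b.size,
                        location_show=float(np.median(a)),
                        location_noshow=float(np.median(b)),
                    )
                )
    return results
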