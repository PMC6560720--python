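"""Cluster evaluation against fall-risk correlates.

Elderly participants in the two clusters are compared on age, weekly
physical-activity volume (MET-min/week) and Timed Up and Go performance
with two-sided Wilcoxon rank-sum tests at alpha = 0.05.  TUG performance
is the mean of trials 2 and 3 (trial 1 is familiarization); 13.5 s or
more flags a high fall risk.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .clustering import ClusterAssignment, HIGHER_RISK, LOWER_RISK
from .depth_io import CohortTable

__all__ = [
    "RankSumResult",
    "TugAssessment",
    "wilcoxon_rank_sum",
    "classify_tug",
    "met_minutes_per_week",
    "compare_clusters",
    "holm_adjust",
    "DEFAULT_ALPHA",
    "DEFAULT_TUG_THRESHOLD_S",
    "EXACT_MAX_N",
]

DEFAULT_ALPHA = 0.05
DEFAULT_TUG_THRESHOLD_S = 13.5
#: Largest combined sample size for the exact (enumeration) p-value path.
EXACT_MAX_N = 12


@dataclass(frozen=True)
class RankSumResult:
    """Wilcoxon rank-sum outcome: W is the rank-sum of the first sample."""

    statistic: float
    p_value: float
    method: str  # "exact" | "normal_approximation"
    n1: int
    n2: int


@dataclass(frozen=True)
class TugAssessment:
    """Timed Up and Go outcome against the clinical threshold."""

    mean_time: float  # seconds, mean of trials 2 and 3
    risk: str  # "low" | "high"
    threshold: float = DEFAULT_TUG_THRESHOLD_S


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test with midranks for ties.

    The p-value is exact (full enumeration of the rank-sum null
    distribution) when the combined sample size is at most ``EXACT_MAX_N``
    and there are no ties; otherwise a normal approximation with tie and
    continuity corrections is used.  Two-sided p = min(1, 2 x one-sided).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    exact = (n1 + n2 <= EXACT_MAX_N) and not has_ties
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    # U1 = W - n1(n1+1)/2; report the classical rank-sum W of the first sample.
    w = float(res.statistic) + n1 * (n1 + 1) / 2.0
    return RankSumResult(
        statistic=w,
        p_value=float(res.pvalue),
        method="exact" if exact else "normal_approximation",
        n1=int(n1),
        n2=int(n2),
    )


def classify_tug(
    trials: Sequence[float], threshold: float = DEFAULT_TUG_THRESHOLD_S
) -> TugAssessment:
    """Classify fall risk from three TUG trials.

    The first trial is familiarization and is discarded; performance is
    the mean of trials 2 and 3.  A mean of ``threshold`` seconds or more
    means high risk.
    """
    if len(trials) != 3:
        raise ValueError("exactly three TUG trials are required")
    t = np.asarray(trials, dtype=float)
    if np.any(t <= 0):
        raise ValueError("TUG durations must be positive")
    mean_time = float((t[1] + t[2]) / 2.0)
    risk = "high" if mean_time >= threshold else "low"
    return TugAssessment(mean_time=mean_time, risk=risk, threshold=threshold)


def met_minutes_per_week(activities: Iterable[tuple[float, float]]) -> float:
    """Weekly physical-activity volume: sum of MET level x minutes/week.

    MET levels are multiples of resting energy expenditure (rest = 1 MET),
    so levels below 1 are rejected.
    """
    total = 0.0
    for met_level, minutes in activities:
        if met_level < 1:
            raise ValueError("MET level below resting expenditure (1 MET)")
        if minutes < 0:
            raise ValueError("minutes per week must be non-negative")
        total += met_level * minutes
    return total


def compare_clusters(
    cohort: CohortTable,
    assignment: ClusterAssignment,
    variable: str,
) -> RankSumResult:
    """Rank-sum comparison of a fall-risk correlate between clusters.

    Only elderly participants enter the comparison — including the young
    would artificially inflate the difference.  ``variable`` is one of
    ``age``, ``activity`` or ``tug`` (mean of the last two trials).  The
    first sample is the higher-risk cluster.
    """
    if not assignment.relevant:
        raise ValueError("cluster risk labels are undetermined; cannot compare")
    values = cohort.variable(variable)
    elderly = set(cohort.elderly_ids)
    high = [p for p in assignment.members(assignment.cluster_of_risk(HIGHER_RISK)) if p in elderly]
    low = [p for p in assignment.members(assignment.cluster_of_risk(LOWER_RISK)) if p in elderly]
    if not high or not low:
        raise ValueError("a cluster has no elderly members")
    return wilcoxon_rank_sum(values.loc[high].to_numpy(), values.loc[low].to_numpy())


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (optional multiple-testing control)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted
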