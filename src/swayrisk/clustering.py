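"""Two-cluster cohort stratification with reference-group labeling.

Participants are partitioned by K-means (K=2) on standardized balance
parameters, per task and per parameter subset.  The young participants
act as a reference group: a model is *relevant* only when every young
participant lands in one cluster, and that cluster is then labeled the
better-balance / lower-fall-risk group.  A split of the reference group
(the young-split counts) marks the model as not relevant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .depth_io import PARAMETER_NAMES, CohortTable

__all__ = [
    "FeatureMatrix",
    "ClusterAssignment",
    "standardize",
    "kmeans_two",
    "label_by_reference",
    "cluster_all_tasks",
    "DEFAULT_SUBSETS",
]

#: The paper's four models per task: each parameter alone, then all three.
DEFAULT_SUBSETS: tuple[tuple[str, ...], ...] = (
    ("centroid_variability",),
    ("centroid_max_speed",),
    ("max_dispersion",),
    PARAMETER_NAMES,
)

LOWER_RISK = "lower_risk"
HIGHER_RISK = "higher_risk"
UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class FeatureMatrix:
    """Participants x parameters, column-standardized (mean 0, sample SD 1)."""

    values: pd.DataFrame
    constant_columns: tuple[str, ...] = ()

    @property
    def ids(self) -> list[str]:
        return [str(i) for i in self.values.index]


@dataclass(frozen=True)
class ClusterAssignment:
    """A two-cluster partition with risk labels and reference-split counts."""

    labels: Mapping[str, str]  # participant id -> "A" | "B"
    centroids: pd.DataFrame  # index ("A", "B") x parameter columns
    inertia: float
    risk_labels: Mapping[str, str] = field(
        default_factory=lambda: {"A": UNDETERMINED, "B": UNDETERMINED}
    )
    young_split: tuple[int, int] | None = None

    @property
    def relevant(self) -> bool:
        return UNDETERMINED not in self.risk_labels.values()

    def members(self, cluster: str) -> list[str]:
        return [pid for pid, c in self.labels.items() if c == cluster]

    def cluster_of_risk(self, risk: str) -> str:
        for cluster, label in self.risk_labels.items():
            if label == risk:
                return cluster
        raise KeyError(f"no cluster labeled {risk!r}")


def standardize(raw: pd.DataFrame) -> FeatureMatrix:
    """Per-column z-scores with sample SD (divisor n-1).

    Constant columns carry no information; they are mapped to all-zero and
    flagged (with a warning) rather than producing NaNs.
    """
    if len(raw) < 2:
        raise ValueError("standardization needs at least 2 participants")
    values = raw.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("feature table contains missing or non-finite values")
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    constant = sd == 0
    sd_safe = np.where(constant, 1.0, sd)
    z = (values - mean) / sd_safe
    z[:, constant] = 0.0
    constant_cols = tuple(raw.columns[constant])
    if constant_cols:
        warnings.warn(f"constant feature columns standardized to zero: {constant_cols}")
    out = pd.DataFrame(z, index=raw.index.astype(str), columns=raw.columns)
    return FeatureMatrix(values=out, constant_columns=constant_cols)


def _display_order(centroids: np.ndarray, columns: Sequence[str]) -> np.ndarray:
    """Cluster display names: A = larger/faster movements.

    Ordered by descending centroid coordinate of ``centroid_max_speed``
    when that parameter is in the model, else by descending centroid norm.
    """
    cols = list(columns)
    if "centroid_max_speed" in cols:
        key = centroids[:, cols.index("centroid_max_speed")]
    else:
        key = np.linalg.norm(centroids, axis=1)
    return np.argsort(-key, kind="stable")


#: Below this row count the optimal 2-partition is found by enumeration.
EXACT_KMEANS_MAX_N = 12


def _exact_two_partition(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Globally minimum-inertia 2-partition by exhaustive enumeration.

    Feasible for tiny cohorts (2^(n-1)-1 splits); ties broken by the
    lexicographically smallest membership vector, so fully deterministic.
    """
    n = len(x)
    best_labels, best_centers, best_inertia = None, None, np.inf
    for bits in range(1, 2 ** (n - 1)):
        member = (bits >> np.arange(n)) & 1 == 1
        a, b = x[member], x[~member]
        ca, cb = a.mean(axis=0), b.mean(axis=0)
        inertia = ((a - ca) ** 2).sum() + ((b - cb) ** 2).sum()
        if inertia < best_inertia - 1e-15:
            best_labels = member.astype(int)
            best_centers = np.vstack([cb, ca])  # label 0 -> cb, label 1 -> ca
            best_inertia = float(inertia)
    return best_labels, best_centers, best_inertia


def kmeans_two(features: FeatureMatrix, seed: int = 0, n_restarts: int = 10) -> ClusterAssignment:
    """Minimum-inertia 2-partition of the standardized features.

    For more than ``EXACT_KMEANS_MAX_N`` rows: Lloyd iterations to
    convergence, k-means++ seeding, best of ``n_restarts`` by inertia,
    deterministic given ``seed``.  At or below that size the optimal
    partition is found exactly by enumeration (Lloyd's local optima are
    a real risk on tiny inputs, and the exhaustive search is instant).
    """
    x = features.values.to_numpy(dtype=float)
    if len(np.unique(x, axis=0)) < 2:
        raise ValueError("all rows identical; a 2-partition is degenerate")
    if len(x) <= EXACT_KMEANS_MAX_N:
        raw_labels, centers, inertia = _exact_two_partition(x)
    else:
        km = KMeans(
            n_clusters=2,
            n_init=n_restarts,
            random_state=seed,
            tol=1e-8,
            max_iter=300,
        ).fit(x)
        raw_labels, centers, inertia = km.labels_, km.cluster_centers_, float(km.inertia_)
    order = _display_order(centers, features.values.columns)
    name_of = {int(order[0]): "A", int(order[1]): "B"}
    labels = {pid: name_of[int(lab)] for pid, lab in zip(features.ids, raw_labels)}
    centroids = pd.DataFrame(
        centers[order], index=["A", "B"], columns=features.values.columns
    )
    return ClusterAssignment(labels=labels, centroids=centroids, inertia=inertia)


def label_by_reference(
    assignment: ClusterAssignment, reference_ids: Iterable[str]
) -> ClusterAssignment:
    """Apply the reference-group rule.

    If one cluster contains every reference (young) participant, that
    cluster is labeled lower-risk and the other higher-risk; otherwise
    both stay undetermined and the split counts are recorded.
    """
    refs = [str(r) for r in reference_ids]
    if not refs:
        raise ValueError("reference id set is empty")
    unknown = [r for r in refs if r not in assignment.labels]
    if unknown:
        raise KeyError(f"reference ids not in assignment: {unknown}")
    in_a = sum(assignment.labels[r] == "A" for r in refs)
    in_b = len(refs) - in_a
    if in_a == 0:
        risk = {"A": HIGHER_RISK, "B": LOWER_RISK}
    elif in_b == 0:
        risk = {"A": LOWER_RISK, "B": HIGHER_RISK}
    else:
        risk = {"A": UNDETERMINED, "B": UNDETERMINED}
    return replace(assignment, risk_labels=risk, young_split=(in_a, in_b))


def cluster_all_tasks(
    cohort: CohortTable,
    parameter_subsets: Sequence[Sequence[str]] = DEFAULT_SUBSETS,
    tasks: Sequence[int] | None = None,
    seed: int = 0,
    n_restarts: int = 10,
) -> tuple[pd.DataFrame, dict[tuple[int, tuple[str, ...]], ClusterAssignment]]:
    """Run standardize -> kmeans_two -> label_by_reference per (task, subset).

    Returns a report table (task, subset, young_in_A, young_in_B,
    relevant) mirroring the per-task reference-split summary, plus the
    assignment objects keyed by (task, subset).
    """
    if tasks is None:
        tasks = cohort.tasks_present()
    if not tasks:
        raise ValueError("cohort has no complete task feature columns")
    young = cohort.young_ids
    rows = []
    assignments: dict[tuple[int, tuple[str, ...]], ClusterAssignment] = {}
    for task in tasks:
        for subset in parameter_subsets:
            subset = tuple(subset)
            raw = cohort.task_features(task, subset)
            assignment = label_by_reference(
                kmeans_two(standardize(raw), seed=seed, n_restarts=n_restarts), young
            )
            assignments[(task, subset)] = assignment
            in_a, in_b = assignment.young_split
            rows.append(
                {
                    "task": task,
                    "subset": "+".join(subset),
                    "young_in_A": in_a,
                    "young_in_B": in_b,
                    "relevant": assignment.relevant,
                }
            )
    return pd.DataFrame(rows), assignments
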