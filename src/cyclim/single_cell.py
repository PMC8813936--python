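"""Single-cell phenotype analysis: per-marker 0-1 scaling, k-means and
hierarchical clustering, rule-based group assignment, sequential gating for
rare populations, and marker-pair co-expression.

Feature matrices are pandas DataFrames with one row per segmented cell and
one column per marker (background-subtracted MFIs).  All MFIs are scaled
to [0, 1] per marker before clustering so that bright and dim stains
contribute comparably.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import AgglomerativeClustering, KMeans

from .errors import ConfigError, InputError

__all__ = [
    "CellFeatureMatrix",
    "ClusterResult",
    "GroupRule",
    "PairCorrelation",
    "scale_unit_interval",
    "kmeans_cluster",
    "hierarchical_cluster",
    "assign_groups",
    "gate_sequential",
    "pair_correlation",
]


@dataclass
class CellFeatureMatrix:
    """Cells x markers MFI matrix with optional spatial centroids."""

    features: pd.DataFrame
    centroids: pd.DataFrame | None = None  # columns cy, cx, same index

    @property
    def markers(self) -> list[str]:
        return list(self.features.columns)

    @property
    def n_cells(self) -> int:
        return len(self.features)


@dataclass
class ClusterResult:
    """Per-cell cluster assignments (1..k) plus per-cluster mean profiles."""

    method: str
    k: int
    assignments: pd.Series
    cluster_means: pd.DataFrame
    seed: int | None = None
    linkage: str | None = None
    groups: dict[int, str] = field(default_factory=dict)


@dataclass(frozen=True)
class GroupRule:
    """One ordered grouping rule on cluster mean profiles.

    A cluster matches when at least one (``mode="any"``) or all
    (``mode="all"``) listed markers have a cluster-mean at or above the
    rule's threshold.  E.g. B cells by IgM-or-IgD, T cells by TCR.
    """

    group: str
    thresholds: dict[str, float]
    mode: str = "any"


@dataclass
class PairCorrelation:
    """Pearson co-expression of one marker pair across cells."""

    marker_x: str
    marker_y: str
    r: float
    p_value: float
    n: int
    alpha: float
    significant: bool


def _as_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, CellFeatureMatrix):
        return matrix.features
    return matrix


def scale_unit_interval(matrix,
                        clip_percentiles: tuple[float, float] | None = None
                        ) -> pd.DataFrame:
    """Per-marker min-max scaling to [0, 1].

    With ``clip_percentiles = (low, high)`` values are first clipped to the
    given per-marker percentiles so isolated outliers do not compress the
    bulk of the distribution.  Constant markers map to 0.
    """
    df = _as_frame(matrix)
    if len(df) < 1:
        raise InputError("need at least one cell")
    values = df.to_numpy(dtype=float)
    if clip_percentiles is not None:
        lo, hi = clip_percentiles
        lo_v = np.percentile(values, lo, axis=0)
        hi_v = np.percentile(values, hi, axis=0)
        values = np.clip(values, lo_v, hi_v)
    mins = values.min(axis=0)
    span = values.max(axis=0) - mins
    span_safe = np.where(span == 0, 1.0, span)
    scaled = (values - mins) / span_safe
    scaled[:, span == 0] = 0.0
    return pd.DataFrame(scaled, index=df.index, columns=df.columns)


def _cluster_means(df: pd.DataFrame, assignments: np.ndarray, k: int) -> pd.DataFrame:
    means = df.groupby(pd.Series(assignments, index=df.index)).mean()
    return means.reindex(range(1, k + 1))


def kmeans_cluster(matrix, k: int = 40, seed: int | None = 0,
                   n_restarts: int = 10) -> ClusterResult:
    """k-means phenotype clustering (40 clusters by default).

    Runs ``n_restarts`` k-means++ initializations and keeps the lowest-
    inertia solution; deterministic for a fixed seed.
    """
    df = _as_frame(matrix)
    if len(df) < k:
        raise InputError(f"need at least k={k} cells, got {len(df)}")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(df.to_numpy(dtype=float)) + 1
    assignments = pd.Series(labels, index=df.index, name="cluster")
    return ClusterResult(method="kmeans", k=k, assignments=assignments,
                         cluster_means=_cluster_means(df, labels, k), seed=seed)


def hierarchical_cluster(matrix, k: int = 20,
                         linkage: str = "ward") -> ClusterResult:
    """Agglomerative clustering on Euclidean distances, cut at k clusters.

    The per-cluster mean profiles are the rows of the marker-expression
    heatmap this analysis feeds.
    """
    df = _as_frame(matrix)
    if len(df) < k:
        raise InputError(f"need at least k={k} cells, got {len(df)}")
    model = AgglomerativeClustering(n_clusters=k, linkage=linkage)
    labels = model.fit_predict(df.to_numpy(dtype=float)) + 1
    assignments = pd.Series(labels, index=df.index, name="cluster")
    return ClusterResult(method="hierarchical", k=k, assignments=assignments,
                         cluster_means=_cluster_means(df, labels, k),
                         linkage=linkage)


def assign_groups(result: ClusterResult, rules: list[GroupRule],
                  unassigned: str = "unassigned") -> ClusterResult:
    """Label clusters by the first matching rule on their mean profile.

    Rules are applied in order (a cluster satisfying both the B-cell and
    T-cell predicates takes whichever comes first); clusters matching no
    rule are labeled ``unassigned`` — typically the very-low-staining
    stromal remainder.
    """
    means = result.cluster_means
    for rule in rules:
        unknown = [m for m in rule.thresholds if m not in means.columns]
        if unknown:
            raise ConfigError(f"rule {rule.group!r} references unknown "
                              f"markers {unknown}")
        if rule.mode not in ("any", "all"):
            raise ConfigError(f"unknown rule mode {rule.mode!r}")
    groups: dict[int, str] = {}
    for cluster_id, profile in means.iterrows():
        label = unassigned
        for rule in rules:
            hits = [profile[m] >= t for m, t in rule.thresholds.items()]
            if (any(hits) if rule.mode == "any" else all(hits)):
                label = rule.group
                break
        groups[int(cluster_id)] = label
    result.groups = groups
    return result


def gate_sequential(matrix, gates: list[tuple[str, float, float]]
                    ) -> tuple[pd.Index, list[int]]:
    """Ordered interval gating: keep cells with marker value in [low, high].

    Returns the surviving cell index and the survivor count after each
    gate.  An empty gate list returns the full set — the strategy narrows
    from everything.  This is how rare populations (tens of cells among
    ~10^4) are pulled out of a feature table.
    """
    df = _as_frame(matrix)
    for marker, _, _ in gates:
        if marker not in df.columns:
            raise ConfigError(f"gate references unknown marker {marker!r}")
    surviving = df
    counts: list[int] = []
    for marker, low, high in gates:
        surviving = surviving[(surviving[marker] >= low)
                              & (surviving[marker] <= high)]
        counts.append(len(surviving))
    return surviving.index, counts


def pair_correlation(matrix, marker_x: str, marker_y: str,
                     alpha: float = 0.01) -> PairCorrelation:
    """Pearson co-expression of two markers with an exact t-based p-value.

    Pearson r is invariant to per-marker affine rescaling, so it does not
    matter whether raw or 0-1-scaled MFIs are supplied.
    """
    df = _as_frame(matrix)
    for m in (marker_x, marker_y):
        if m not in df.columns:
            raise ConfigError(f"unknown marker {m!r}")
    x = df[marker_x].to_numpy(dtype=float)
    y = df[marker_y].to_numpy(dtype=float)
    if len(x) < 3:
        raise InputError("need at least 3 cells")
    if np.std(x) == 0 or np.std(y) == 0:
        raise InputError("zero variance in a marker: correlation undefined")
    res = stats.pearsonr(x, y)
    r, p = float(res.statistic), float(res.pvalue)
    return PairCorrelation(marker_x=marker_x, marker_y=marker_y, r=r,
                           p_value=p, n=len(x), alpha=alpha,
                           significant=bool(p < alpha))
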