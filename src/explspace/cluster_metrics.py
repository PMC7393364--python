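"""Cluster validity indices and chance-corrected partition agreement.

From-scratch implementations of the four statistics used to compare the raw
feature space with the explanation space:

* Davies-Bouldin index — mean over clusters of the worst-case ratio of summed
  intra-cluster dispersions to inter-centroid distance (lower is better);
* Calinski-Harabasz index — between/within dispersion ratio with
  degree-of-freedom normalisation (higher is better);
* Silhouette coefficient — per-sample contrast of mean intra-cluster distance
  against the nearest other cluster, averaged (higher is better);
* Adjusted Mutual Information — mutual information between two partitions,
  corrected by its exact expectation under the permutation (hypergeometric)
  model and normalised by the partition entropies.

Distances are Euclidean throughout; entropies use natural logarithms (AMI is
invariant to the base).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.special import gammaln

from .embed import ClusterPartition

__all__ = [
    "MetricGridCell",
    "davies_bouldin",
    "calinski_harabasz",
    "silhouette",
    "adjusted_mutual_information",
    "grid_to_long_csv",
    "grid_to_wide_csv",
]

METRICS = ("davies_bouldin", "calinski_harabasz", "silhouette", "adjusted_mi")


@dataclass
class MetricGridCell:
    """One row of the benchmark grid: a (space, reducer) pair with its four
    evaluation statistics."""

    space: str  # "feature" or "explanation"
    reducer: str  # "none", "pca", "isomap", "tsne"
    davies_bouldin: float
    calinski_harabasz: float
    silhouette: float
    adjusted_mi: float

    def metric(self, name: str) -> float:
        return getattr(self, name)


def _as_labels(labels) -> np.ndarray:
    if isinstance(labels, ClusterPartition):
        return labels.labels
    return np.asarray(labels)


def _split_by_cluster(X: np.ndarray, labels: np.ndarray):
    values = np.unique(labels)
    return values, [X[labels == v] for v in values]


def davies_bouldin(X: np.ndarray, labels) -> float:
    """DB = (1/k) sum_i max_{j != i} (s_i + s_j) / d(mu_i, mu_j), where s_i is
    the mean distance of cluster-i points to their centroid."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = _as_labels(labels)
    values, groups = _split_by_cluster(X, labels)
    k = len(values)
    if k < 2:
        raise ValueError("Davies-Bouldin needs at least two clusters")
    centroids = np.array([g.mean(axis=0) for g in groups])
    s = np.array(
        [np.linalg.norm(g - c, axis=1).mean() for g, c in zip(groups, centroids)]
    )
    d = cdist(centroids, centroids)
    total = 0.0
    for i in range(k):
        ratios = []
        for j in range(k):
            if j == i:
                continue
            if d[i, j] == 0:
                if s[i] + s[j] > 0:
                    raise ZeroDivisionError(
                        f"clusters {values[i]} and {values[j]} share a centroid "
                        "with nonzero dispersion"
                    )
                ratios.append(0.0)
            else:
                ratios.append((s[i] + s[j]) / d[i, j])
        total += max(ratios)
    return total / k


def calinski_harabasz(X: np.ndarray, labels) -> float:
    """CH = [B/(k-1)] / [W/(n-k)] with B the between-cluster and W the
    within-cluster sum of squared distances.

    W = 0 (every cluster a single point set of identical rows) returns +inf.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = _as_labels(labels)
    values, groups = _split_by_cluster(X, labels)
    n, k = X.shape[0], len(values)
    if not 2 <= k <= n - 1:
        raise ValueError(f"Calinski-Harabasz needs 2 <= k <= n-1, got k={k}, n={n}")
    mu = X.mean(axis=0)
    B = sum(len(g) * float(np.sum((g.mean(axis=0) - mu) ** 2)) for g in groups)
    W = sum(float(np.sum((g - g.mean(axis=0)) ** 2)) for g in groups)
    if W == 0.0:
        return float("inf")
    return (B / (k - 1)) / (W / (n - k))


def silhouette(X: np.ndarray, labels) -> float:
    """Mean over samples of (b - a) / max(a, b); a is the mean intra-cluster
    distance excluding self, b the smallest mean distance to another cluster.
    Points in singleton clusters score 0."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = _as_labels(labels)
    values, _ = _split_by_cluster(X, labels)
    n, k = X.shape[0], len(values)
    if not 2 <= k <= n - 1:
        raise ValueError(f"silhouette needs 2 <= k <= n-1, got k={k}, n={n}")
    D = cdist(X, X)
    scores = np.zeros(n)
    masks = {v: labels == v for v in values}
    sizes = {v: int(masks[v].sum()) for v in values}
    for i in range(n):
        own = labels[i]
        if sizes[own] == 1:
            scores[i] = 0.0
            continue
        a = D[i, masks[own]].sum() / (sizes[own] - 1)
        b = min(D[i, masks[v]].mean() for v in values if v != own)
        scores[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return float(scores.mean())


def _entropy(counts: np.ndarray, n: int) -> float:
    p = counts[counts > 0] / n
    return float(-(p * np.log(p)).sum())


def _mutual_information(table: np.ndarray, n: int) -> float:
    a = table.sum(axis=1)
    b = table.sum(axis=0)
    mi = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            nij = table[i, j]
            if nij > 0:
                mi += (nij / n) * np.log(n * nij / (a[i] * b[j]))
    return float(mi)


def _expected_mutual_information(a: np.ndarray, b: np.ndarray, n: int) -> float:
    """Exact E[MI] under the permutation model: the sum over every admissible
    contingency-cell count weighted by its hypergeometric probability."""
    emi = 0.0
    lg = gammaln
    for ai in a:
        for bj in b:
            lo = max(1, ai + bj - n)
            hi = min(ai, bj)
            for nij in range(lo, hi + 1):
                log_p = (
                    lg(ai + 1)
                    + lg(bj + 1)
                    + lg(n - ai + 1)
                    + lg(n - bj + 1)
                    - lg(n + 1)
                    - lg(nij + 1)
                    - lg(ai - nij + 1)
                    - lg(bj - nij + 1)
                    - lg(n - ai - bj + nij + 1)
                )
                emi += (nij / n) * np.log(n * nij / (ai * bj)) * np.exp(log_p)
    return float(emi)


def adjusted_mutual_information(a, b, normalizer: str = "arithmetic") -> float:
    """AMI = (MI - E[MI]) / (norm(H(a), H(b)) - E[MI]).

    The default normaliser is the arithmetic mean of the two partition
    entropies; ``normalizer="max"`` selects the max convention.  Identical
    partitions score exactly 1.0; a single-cluster partition scores 0.0
    against anything (MI and E[MI] both vanish).
    """
    a = _as_labels(a)
    b = _as_labels(b)
    if a.shape[0] != b.shape[0]:
        raise ValueError("partitions must have equal length")
    n = a.shape[0]
    if n == 0:
        raise ValueError("empty partitions")
    av, a_idx = np.unique(a, return_inverse=True)
    bv, b_idx = np.unique(b, return_inverse=True)
    # both trivial partitions (all one cluster, or all singletons): perfect
    # agreement by convention
    if (len(av) == len(bv) == 1) or (len(av) == len(bv) == n):
        return 1.0
    table = np.zeros((len(av), len(bv)), dtype=np.int64)
    np.add.at(table, (a_idx, b_idx), 1)
    a_counts = table.sum(axis=1)
    b_counts = table.sum(axis=0)
    mi = _mutual_information(table, n)
    emi = _expected_mutual_information(a_counts, b_counts, n)
    ha, hb = _entropy(a_counts, n), _entropy(b_counts, n)
    if normalizer == "arithmetic":
        norm = 0.5 * (ha + hb)
    elif normalizer == "max":
        norm = max(ha, hb)
    else:
        raise ValueError("normalizer must be 'arithmetic' or 'max'")
    denom = norm - emi
    if denom == 0.0:
        return 1.0 if mi >= norm else 0.0
    # match the sign-safe guard of the standard formulation for tiny denominators
    if denom < 0:
        denom = min(denom, -np.finfo(float).eps)
    else:
        denom = max(denom, np.finfo(float).eps)
    return float((mi - emi) / denom)


def grid_to_long_csv(cells: list[MetricGridCell], path, dataset: str = "synthetic") -> None:
    """Long-format table: (dataset, space, reducer, metric, value)."""
    rows = [
        {
            "dataset": dataset,
            "space": c.space,
            "reducer": c.reducer,
            "metric": m,
            "value": c.metric(m),
        }
        for c in cells
        for m in METRICS
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def grid_to_wide_csv(cells: list[MetricGridCell], path, dataset: str = "synthetic") -> None:
    """Wide table shaped like the benchmark grid: one row per
    (reducer, space) with the four metrics as columns."""
    rows = [
        {
            "dataset": dataset,
            "reducer": c.reducer,
            "space": c.space,
            **{m: c.metric(m) for m in METRICS},
        }
        for c in cells
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
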