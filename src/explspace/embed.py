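"""Dimensionality-reduction adapters and agglomerative clustering.

The same reducers are applied, with identical settings, to the raw feature
space and to the explanation space, so any difference in downstream cluster
structure is attributable to the representation and not to the reducer.
PCA is computed here directly (centred SVD with a fixed sign convention);
the nonlinear reducers delegate to scikit-learn with pinned numerical
settings so behaviour is stable across library versions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

REDUCERS = ("none", "pca", "isomap", "tsne")

ISOMAP_N_NEIGHBORS = 5
TSNE_PERPLEXITY = 30.0
TSNE_LEARNING_RATE = 200.0


@dataclass
class Embedding:
    """Coordinates of a dataset in a (possibly reduced) representation."""

    coords: np.ndarray
    method: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)


@dataclass
class ClusterPartition:
    """Integer cluster assignment with labels in {0..k-1}, all non-empty."""

    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        present = np.unique(self.labels)
        if present.size != self.k or present.min() < 0 or present.max() != self.k - 1:
            raise ValueError(
                f"labels must use every value in 0..{self.k - 1}; found {present}"
            )


def pca_reduce(X: np.ndarray, n_components: int = 2) -> Embedding:
    """Principal-component scores of the column-centred matrix.

    Components are ordered by decreasing explained variance.  The sign of
    each component is fixed so that its largest-magnitude loading is
    positive, making the output fully deterministic.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least two rows")
    if n_components > min(n, p):
        raise ValueError(f"n_components must be <= min(n, p) = {min(n, p)}")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    for j in range(n_components):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] = -Vt[j]
            U[:, j] = -U[:, j]
    coords = U[:, :n_components] * s[:n_components]
    explained = (s**2) / (n - 1)
    return Embedding(
        coords=coords,
        method="pca",
        params={"explained_variance": explained[:n_components].tolist()},
    )


def reduce(X: np.ndarray, method: str = "none", seed: int = 0) -> Embedding:
    """Embed X by one of {none, pca, isomap, tsne} (2 output columns for the
    reduced methods); deterministic under a fixed seed."""
    X = np.asarray(X, dtype=float)
    if method == "none":
        return Embedding(coords=X, method="none", seed=seed)
    if method == "pca":
        emb = pca_reduce(X, n_components=2)
        emb.seed = seed
        return emb
    if method == "isomap":
        from sklearn.manifold import Isomap

        iso = Isomap(n_neighbors=ISOMAP_N_NEIGHBORS, n_components=2)
        coords = iso.fit_transform(X)
        return Embedding(
            coords=coords,
            method="isomap",
            params={"n_neighbors": ISOMAP_N_NEIGHBORS},
            seed=seed,
        )
    if method == "tsne":
        from sklearn.manifold import TSNE

        ts = TSNE(
            n_components=2,
            perplexity=min(TSNE_PERPLEXITY, (X.shape[0] - 1) / 3.0),
            learning_rate=TSNE_LEARNING_RATE,
            init="pca",
            random_state=seed,
        )
        coords = ts.fit_transform(X)
        return Embedding(
            coords=coords,
            method="tsne",
            params={
                "perplexity": float(ts.perplexity),
                "learning_rate": TSNE_LEARNING_RATE,
                "init": "pca",
            },
            seed=seed,
        )
    raise ValueError(f"unknown reducer {method!r}; expected one of {REDUCERS}")


def ward_agglomerative(X: np.ndarray, k: int) -> ClusterPartition:
    """Bottom-up Ward clustering cut at k clusters.

    Merges the pair of clusters whose union minimally increases the total
    within-cluster variance (Lance-Williams recurrence); labels are renamed
    to 0..k-1 in order of first appearance.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n == 0:
        raise ValueError("empty input")
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    if k == n:
        return ClusterPartition(labels=np.arange(n), k=k)
    if k == 1:
        return ClusterPartition(labels=np.zeros(n, dtype=int), k=1)
    Z = linkage(X, method="ward")
    raw = fcluster(Z, t=k, criterion="maxclust")
    labels = _first_appearance_relabel(raw)
    return ClusterPartition(labels=labels, k=int(labels.max()) + 1)


def _first_appearance_relabel(raw: np.ndarray) -> np.ndarray:
    mapping: dict[int, int] = {}
    out = np.empty(raw.shape[0], dtype=int)
    for i, r in enumerate(raw):
        if r not in mapping:
            mapping[r] = len(mapping)
        out[i] = mapping[r]
    return out


def write_embedding_csv(emb: Embedding, path, labels: np.ndarray | None = None) -> None:
    """Scatter-ready CSV: instance id, one column per coordinate and an
    optional subclass label column."""
    df = pd.DataFrame(
        emb.coords, columns=[f"dim{j}" for j in range(emb.coords.shape[1])]
    )
    df.insert(0, "instance_id", np.arange(emb.coords.shape[0]))
    if labels is not None:
        df["label"] = np.asarray(labels)
    df.to_csv(path, index=False)
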