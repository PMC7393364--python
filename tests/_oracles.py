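"""Independent reference implementations used only to verify the package.

Each oracle is deliberately naive (enumeration or O(n^3) scans) and shares no
code with the implementation it checks.
"""

from __future__ import annotations

import numpy as np

from explspace.forest import TreeEnsemble, TreeModel, train_random_forest


def naive_ward_partition(X: np.ndarray, k: int) -> list[frozenset]:
    """O(n^3) bottom-up Ward clustering by direct objective evaluation.

    At every step merge the pair of clusters whose union minimally increases
    the total within-cluster sum of squares: delta(A, B) =
    |A||B| / (|A|+|B|) * ||mean(A) - mean(B)||^2.  Ties break toward the
    smallest pair of cluster indices.  Returns the partition at k clusters
    as a list of frozensets of row indices.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    clusters: list[list[int]] = [[i] for i in range(n)]
    while len(clusters) > k:
        best = None
        best_pair = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = clusters[i], clusters[j]
                ma, mb = X[a].mean(axis=0), X[b].mean(axis=0)
                delta = len(a) * len(b) / (len(a) + len(b)) * float(
                    np.sum((ma - mb) ** 2)
                )
                if best is None or delta < best - 1e-12:
                    best, best_pair = delta, (i, j)
        i, j = best_pair
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return [frozenset(c) for c in clusters]


def partition_as_sets(labels: np.ndarray) -> set[frozenset]:
    labels = np.asarray(labels)
    return {frozenset(np.flatnonzero(labels == v).tolist()) for v in np.unique(labels)}


def enumerate_tree_expectation(
    tree: TreeModel, x: np.ndarray, known: set[int]
) -> float:
    """Expectation of a tree's output by explicit leaf enumeration.

    Walks every root-to-leaf path, multiplying cover fractions at splits on
    unknown features and following x at splits on known features (probability
    1 or 0), then sums value * path-probability over all leaves.
    """
    total = 0.0
    stack = [(0, 1.0)]
    while stack:
        node, prob = stack.pop()
        if prob == 0.0:
            continue
        if tree.is_leaf(node):
            total += prob * float(tree.leaf_value[node])
            continue
        f = int(tree.split_feature[node])
        l, r = int(tree.children_left[node]), int(tree.children_right[node])
        if f in known:
            goes_left = x[f] <= tree.split_threshold[node]
            stack.append((l, prob if goes_left else 0.0))
            stack.append((r, 0.0 if goes_left else prob))
        else:
            cl, cr = float(tree.node_cover[l]), float(tree.node_cover[r])
            stack.append((l, prob * cl / (cl + cr)))
            stack.append((r, prob * cr / (cl + cr)))
    return total


def random_small_forest(
    rng: np.random.Generator,
    n_features: int | None = None,
    n_samples: int = 40,
    n_trees: int | None = None,
    max_depth: int = 4,
) -> tuple[TreeEnsemble, int]:
    """A small trained forest on random data, for oracle sweeps."""
    p = int(n_features if n_features is not None else rng.integers(2, 9))
    t = int(n_trees if n_trees is not None else rng.integers(1, 11))
    X = rng.standard_normal((n_samples, p))
    w = rng.standard_normal(p)
    y = (X @ w + 0.5 * rng.standard_normal(n_samples) > 0).astype(int)
    if y.min() == y.max():  # degenerate labelings make trivial trees; flip one
        y[0] = 1 - y[0]
    model = train_random_forest(
        X, y, n_trees=t, max_depth=max_depth, seed=int(rng.integers(0, 2**31 - 1))
    )
    return model, p
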