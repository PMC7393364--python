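"""Bagged binary decision trees (random forest) in array form.

The classifier behind the binary diagnostic task.  Trees are grown on
bootstrap resamples by recursive partitioning that maximises the Gini
impurity decrease over ``mtry`` candidate features per node; every node
stores its positive-class weight fraction (``leaf_value``) and the training
weight reaching it (``node_cover``), which is exactly the information the
path-dependent Shapley attribution needs.

The ensemble is serialisable to a documented JSON schema (per-tree parallel
arrays plus ``n_features`` and ``base_value``) so models can be moved between
processes and inspected as text.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TreeModel",
    "TreeEnsemble",
    "train_random_forest",
    "predict_proba",
    "serialize_ensemble",
    "deserialize_ensemble",
]

_LEAF = -1


@dataclass
class TreeModel:
    """A single binary decision tree in parallel-array form.

    ``children_left[i] == children_right[i] == -1`` marks node ``i`` as a
    leaf.  ``leaf_value`` is the fraction of positive-class training weight
    reaching the node (defined at every node, not only leaves) and
    ``node_cover`` the total training weight reaching it.  Routing is
    "go left iff x[feature] <= threshold".
    """

    children_left: np.ndarray
    children_right: np.ndarray
    split_feature: np.ndarray
    split_threshold: np.ndarray
    leaf_value: np.ndarray
    node_cover: np.ndarray

    def __post_init__(self) -> None:
        self.children_left = np.asarray(self.children_left, dtype=np.int64)
        self.children_right = np.asarray(self.children_right, dtype=np.int64)
        self.split_feature = np.asarray(self.split_feature, dtype=np.int64)
        self.split_threshold = np.asarray(self.split_threshold, dtype=float)
        self.leaf_value = np.asarray(self.leaf_value, dtype=float)
        self.node_cover = np.asarray(self.node_cover, dtype=float)

    @property
    def n_nodes(self) -> int:
        return self.children_left.shape[0]

    def is_leaf(self, i: int) -> bool:
        return self.children_left[i] == _LEAF

    def validate(self) -> None:
        """Check structural invariants; raise ValueError naming the node."""
        n = self.n_nodes
        arrays = (
            self.children_right,
            self.split_feature,
            self.split_threshold,
            self.leaf_value,
            self.node_cover,
        )
        if any(a.shape[0] != n for a in arrays):
            raise ValueError("tree arrays have inconsistent lengths")
        seen = np.zeros(n, dtype=bool)
        stack = [0]
        while stack:
            i = stack.pop()
            if i < 0 or i >= n:
                raise ValueError(f"node index {i} out of range")
            if seen[i]:
                raise ValueError(f"node {i} reachable twice (cycle or shared child)")
            seen[i] = True
            left, right = self.children_left[i], self.children_right[i]
            if (left == _LEAF) != (right == _LEAF):
                raise ValueError(f"node {i} has exactly one child")
            if not 0.0 <= self.leaf_value[i] <= 1.0:
                raise ValueError(f"node {i} leaf_value outside [0, 1]")
            if self.node_cover[i] < 0:
                raise ValueError(f"node {i} has negative cover")
            if left != _LEAF:
                child_cover = self.node_cover[left] + self.node_cover[right]
                if not np.isclose(child_cover, self.node_cover[i], rtol=1e-9, atol=1e-9):
                    raise ValueError(
                        f"node {i}: child covers {child_cover} do not sum to "
                        f"parent cover {self.node_cover[i]}"
                    )
                stack.extend((int(left), int(right)))
        if not seen.all():
            orphan = int(np.flatnonzero(~seen)[0])
            raise ValueError(f"node {orphan} unreachable from the root")

    def max_depth(self) -> int:
        depth = np.zeros(self.n_nodes, dtype=np.int64)
        best = 0
        stack = [0]
        while stack:
            i = stack.pop()
            best = max(best, int(depth[i]))
            if not self.is_leaf(i):
                l, r = int(self.children_left[i]), int(self.children_right[i])
                depth[l] = depth[r] = depth[i] + 1
                stack.extend((l, r))
        return best

    def decision_path_values(self, X: np.ndarray) -> np.ndarray:
        """Leaf value each row of X routes to."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        node = np.zeros(X.shape[0], dtype=np.int64)
        active = self.children_left[node] != _LEAF
        while active.any():
            idx = np.flatnonzero(active)
            cur = node[idx]
            go_left = X[idx, self.split_feature[cur]] <= self.split_threshold[cur]
            node[idx] = np.where(
                go_left, self.children_left[cur], self.children_right[cur]
            )
            active = self.children_left[node] != _LEAF
        return self.leaf_value[node]


@dataclass
class TreeEnsemble:
    """Probability-averaging forest: prediction is the unweighted mean over
    trees of the leaf positive fraction; ``base_value`` is the cover-weighted
    mean leaf value averaged over trees (the model's expected output)."""

    trees: list[TreeModel]
    n_features: int
    base_value: float
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for t in self.trees:
            used = t.split_feature[t.children_left != _LEAF]
            if used.size and used.max() >= self.n_features:
                raise ValueError("tree splits on a feature index >= n_features")

    @property
    def n_trees(self) -> int:
        return len(self.trees)


def _grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    rows: np.ndarray,
    mtry: int,
    min_leaf: int,
    max_depth: int | None,
    rng: np.random.Generator,
) -> TreeModel:
    """Grow one CART tree on the (repeated) row indices ``rows``.

    Split criterion: maximise the decrease in weighted Gini impurity, which is
    equivalent to maximising sum over children of (positive weight)^2 / weight.
    Ties are broken toward the lowest feature index, then lowest threshold
    (features are examined in increasing index order and a new split is
    accepted only on a strict improvement).
    """
    p = X.shape[1]
    children_left: list[int] = []
    children_right: list[int] = []
    split_feature: list[int] = []
    split_threshold: list[float] = []
    leaf_value: list[float] = []
    node_cover: list[float] = []

    def new_node(idx: np.ndarray) -> int:
        wi = w[idx]
        sw = wi.sum()
        sy = float(wi @ y[idx])
        node = len(children_left)
        children_left.append(_LEAF)
        children_right.append(_LEAF)
        split_feature.append(-2)
        split_threshold.append(np.nan)
        leaf_value.append(sy / sw if sw > 0 else 0.0)
        node_cover.append(float(sw))
        return node

    root = new_node(rows)
    stack: list[tuple[int, np.ndarray, int]] = [(root, rows, 0)]
    while stack:
        node, idx, depth = stack.pop()
        wi = w[idx]
        sw = float(wi.sum())
        sy = float(wi @ y[idx])
        pure = sy <= 0.0 or sy >= sw
        if (
            pure
            or idx.size < 2 * min_leaf
            or idx.size < 2
            or (max_depth is not None and depth >= max_depth)
        ):
            continue

        # examine features in a random order but accept at most mtry
        # non-constant candidates; report the winner in deterministic
        # (feature, threshold) tie-break order
        feat_order = rng.permutation(p)
        best_score = -1.0  # split scores are always >= 0
        best_feat = -1
        best_thr = np.nan
        tried = 0
        base_score = sy * sy / sw  # score of the unsplit node
        for f in feat_order:
            col = X[idx, f]
            order = np.argsort(col, kind="stable")
            xs = col[order]
            if xs[0] == xs[-1]:
                continue  # constant feature at this node
            tried += 1
            ws = wi[order]
            ys = y[idx][order] * ws
            cw = np.cumsum(ws)[:-1]
            cy = np.cumsum(ys)[:-1]
            # valid split positions: value changes and both sides >= min_leaf
            pos = np.flatnonzero(xs[1:] != xs[:-1])
            if min_leaf > 1:
                pos = pos[(pos + 1 >= min_leaf) & (idx.size - pos - 1 >= min_leaf)]
            if pos.size == 0:
                if tried >= mtry:
                    break
                continue
            lw, ly = cw[pos], cy[pos]
            rw, ry = sw - lw, sy - ly
            scores = ly * ly / lw + ry * ry / rw
            k = int(np.argmax(scores))
            score = float(scores[k])
            thr = float(0.5 * (xs[pos[k]] + xs[pos[k] + 1]))
            better = score > best_score + 1e-12 * max(1.0, abs(best_score))
            tie = not better and np.isclose(score, best_score, rtol=1e-12, atol=1e-12)
            if better or (tie and (f < best_feat or (f == best_feat and thr < best_thr))):
                best_score, best_feat, best_thr = score, int(f), thr
            if tried >= mtry:
                break

        if best_feat < 0 or best_score <= base_score + 1e-12 * max(1.0, base_score):
            continue  # no impurity decrease: stay a leaf

        go_left = X[idx, best_feat] <= best_thr
        left_idx, right_idx = idx[go_left], idx[~go_left]
        l = new_node(left_idx)
        r = new_node(right_idx)
        children_left[node] = l
        children_right[node] = r
        split_feature[node] = best_feat
        split_threshold[node] = best_thr
        stack.append((r, right_idx, depth + 1))
        stack.append((l, left_idx, depth + 1))

    return TreeModel(
        children_left=np.array(children_left),
        children_right=np.array(children_right),
        split_feature=np.array(split_feature),
        split_threshold=np.array(split_threshold),
        leaf_value=np.array(leaf_value),
        node_cover=np.array(node_cover),
    )


def train_random_forest(
    X: np.ndarray,
    y_binary: np.ndarray,
    n_trees: int = 100,
    mtry: int | None = None,
    min_leaf: int = 1,
    max_depth: int | None = None,
    sample_weights: np.ndarray | None = None,
    seed: int = 0,
) -> TreeEnsemble:
    """Train a probability-averaging random forest on a binary task.

    Each tree sees an n-sample bootstrap resample; ``sample_weights`` (if
    given) act as per-instance training weights inside the impurity and the
    covers, equivalent in expectation to inverse-frequency resampling but
    deterministic given the bootstrap.  Defaults follow the conventional
    choices for this classifier family: 100 trees, mtry = ceil(sqrt(p)),
    grow to purity.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y_binary)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X and y_binary have incompatible shapes")
    labels = np.unique(y)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError(f"labels must be binary in {{0, 1}}, got {labels}")
    y = y.astype(float)
    n, p = X.shape
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if mtry is None:
        mtry = int(np.ceil(np.sqrt(p)))
    if not 1 <= mtry <= p:
        raise ValueError(f"mtry must be in [1, {p}]")
    if sample_weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(sample_weights, dtype=float)
        if w.shape != (n,) or (w < 0).any():
            raise ValueError("sample_weights must be non-negative, one per row")

    trees: list[TreeModel] = []
    seeds = np.random.SeedSequence(seed).spawn(n_trees)
    for ss in seeds:
        rng = np.random.default_rng(ss)
        rows = rng.integers(0, n, size=n)
        trees.append(_grow_tree(X, y, w, rows, mtry, min_leaf, max_depth, rng))

    # root leaf_value is already the cover-weighted mean over all leaves
    base = float(np.mean([t.leaf_value[0] for t in trees]))
    return TreeEnsemble(trees=trees, n_features=p, base_value=base)


def predict_proba(model: TreeEnsemble, X: np.ndarray) -> np.ndarray:
    """Mean over trees of the leaf value each row routes to."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"X has {X.shape[1]} columns, model expects {model.n_features}"
        )
    out = np.zeros(X.shape[0])
    for t in model.trees:
        out += t.decision_path_values(X)
    return out / model.n_trees


_SCHEMA_VERSION = 1


def serialize_ensemble(model: TreeEnsemble) -> str:
    """JSON text for a forest: schema version, n_features, base_value and one
    object of parallel arrays per tree."""
    doc = {
        "schema": "explspace-forest",
        "version": _SCHEMA_VERSION,
        "n_features": int(model.n_features),
        "base_value": float(model.base_value),
        "feature_names": list(model.feature_names),
        "trees": [
            {
                "children_left": t.children_left.tolist(),
                "children_right": t.children_right.tolist(),
                "split_feature": t.split_feature.tolist(),
                "split_threshold": [
                    None if np.isnan(v) else v for v in t.split_threshold
                ],
                "leaf_value": t.leaf_value.tolist(),
                "node_cover": t.node_cover.tolist(),
            }
            for t in model.trees
        ],
    }
    return json.dumps(doc)


def deserialize_ensemble(text: str) -> TreeEnsemble:
    """Parse and validate the JSON forest schema; raises ValueError with the
    offending node index on structural violations."""
    doc = json.loads(text)
    if doc.get("schema") != "explspace-forest":
        raise ValueError("not an explspace forest document")
    trees = []
    for t in doc["trees"]:
        tree = TreeModel(
            children_left=t["children_left"],
            children_right=t["children_right"],
            split_feature=t["split_feature"],
            split_threshold=[np.nan if v is None else v for v in t["split_threshold"]],
            leaf_value=t["leaf_value"],
            node_cover=t["node_cover"],
        )
        tree.validate()
        trees.append(tree)
    return TreeEnsemble(
        trees=trees,
        n_features=int(doc["n_features"]),
        base_value=float(doc["base_value"]),
        feature_names=list(doc.get("feature_names", [])),
    )
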