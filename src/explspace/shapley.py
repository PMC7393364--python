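"""Instance-wise Shapley attributions for tree ensembles.

The transformation from feature space into *explanation space*: every
instance is mapped to the vector of Shapley values of the forest's predicted
probability, one value per feature, computed under path-dependent
(cover-weighted) conditional expectations.  Two routes are provided:

* :func:`brute_force_shap` — the defining subset enumeration, exponential in
  the number of features, used as the verification oracle;
* :func:`tree_shap` — the polynomial-time path algorithm, which must agree
  with the oracle to 1e-8 wherever the oracle is feasible.

Attributions explain the probability output of the forest (leaf values are
positive-class fractions), so local accuracy
``base_value + sum_j(phi_j) == predict_proba(x)`` holds exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._treeshap import ensemble_shap_matrix
from .forest import TreeEnsemble, TreeModel, predict_proba

__all__ = [
    "ExplanationMatrix",
    "tree_expected_value",
    "brute_force_shap",
    "tree_shap",
    "explain_matrix",
    "write_explanations_csv",
    "read_explanations_csv",
]

_BRUTE_FORCE_MAX_FEATURES = 12


@dataclass
class ExplanationMatrix:
    """n x p matrix of Shapley attributions plus the model's base value.

    The column count always equals the originating feature space's
    dimensionality, and for every row
    ``base_value + phi[i].sum() == predicted probability of instance i``.
    """

    phi: np.ndarray
    base_value: float
    instance_ids: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.instance_ids = np.asarray(self.instance_ids)
        if self.phi.ndim != 2 or self.phi.shape[0] != self.instance_ids.shape[0]:
            raise ValueError("phi must be 2-D with one instance id per row")
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(self.phi.shape[1])]


def tree_expected_value(tree: TreeModel, x: np.ndarray, known) -> float:
    """Conditional expectation of a tree's output given a feature subset.

    At a split on a known feature, follow x's branch; at a split on an
    unknown feature, average the two children weighted by their training
    covers; at a leaf, return the leaf value.
    """
    x = np.asarray(x, dtype=float)
    known = frozenset(int(k) for k in known)

    def rec(i: int) -> float:
        if tree.is_leaf(i):
            return float(tree.leaf_value[i])
        f = int(tree.split_feature[i])
        l, r = int(tree.children_left[i]), int(tree.children_right[i])
        if f in known:
            return rec(l) if x[f] <= tree.split_threshold[i] else rec(r)
        cl, cr = tree.node_cover[l], tree.node_cover[r]
        return (cl * rec(l) + cr * rec(r)) / (cl + cr)

    return rec(0)


def _coalition_value(model: TreeEnsemble, x: np.ndarray, known) -> float:
    return float(np.mean([tree_expected_value(t, x, known) for t in model.trees]))


def brute_force_shap(
    model: TreeEnsemble, x: np.ndarray, allow_large: bool = False
) -> np.ndarray:
    """Shapley values by explicit enumeration of all feature coalitions.

    phi_j = sum over S subseteq F\\{j} of |S|! (p-|S|-1)! / p! *
    [v(S u {j}) - v(S)].  Exponential in p; refuses p > 12 unless
    ``allow_large`` is set.
    """
    p = model.n_features
    if p > _BRUTE_FORCE_MAX_FEATURES and not allow_large:
        raise ValueError(
            f"brute-force Shapley is exponential: p = {p} > "
            f"{_BRUTE_FORCE_MAX_FEATURES}; pass allow_large=True to override"
        )
    x = np.asarray(x, dtype=float)
    # cache v(S) for every coalition bitmask
    v = np.empty(2**p)
    for mask in range(2**p):
        known = [j for j in range(p) if mask >> j & 1]
        v[mask] = _coalition_value(model, x, known)
    fact = [math.factorial(i) for i in range(p + 1)]
    phi = np.zeros(p)
    for j in range(p):
        rest = [f for f in range(p) if f != j]
        for smask in range(2 ** (p - 1)):
            mask = 0
            size = 0
            for b, f in enumerate(rest):
                if smask >> b & 1:
                    mask |= 1 << f
                    size += 1
            weight = fact[size] * fact[p - size - 1] / fact[p]
            phi[j] += weight * (v[mask | (1 << j)] - v[mask])
    return phi


def _flatten(model: TreeEnsemble):
    offsets = np.zeros(model.n_trees + 1, dtype=np.int64)
    for t, tree in enumerate(model.trees):
        offsets[t + 1] = offsets[t] + tree.n_nodes
    cat = lambda attr: np.concatenate([getattr(t, attr) for t in model.trees])
    return (
        offsets,
        cat("children_left"),
        cat("children_right"),
        cat("split_feature"),
        cat("split_threshold"),
        cat("leaf_value"),
        cat("node_cover"),
        np.array([t.max_depth() for t in model.trees], dtype=np.int64),
    )


def tree_shap(model: TreeEnsemble, x: np.ndarray) -> np.ndarray:
    """Polynomial-time path-dependent Shapley attribution of one instance.

    The ensemble attribution is the mean of per-tree attributions; it sums,
    with the base value, to the predicted probability.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (model.n_features,):
        raise ValueError(
            f"instance has shape {x.shape}, model expects ({model.n_features},)"
        )
    return ensemble_shap_matrix(*_flatten(model), x[None, :])[0]


def explain_matrix(
    model: TreeEnsemble,
    X: np.ndarray,
    instance_ids: np.ndarray | None = None,
    check_local_accuracy: bool = True,
) -> ExplanationMatrix:
    """Explain every row of X: the explanation-space embedding of a dataset.

    Local accuracy is asserted per row (tolerance 1e-8) unless disabled.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"X has {X.shape[1]} columns, model expects {model.n_features}"
        )
    phi = ensemble_shap_matrix(*_flatten(model), X)
    if instance_ids is None:
        instance_ids = np.arange(X.shape[0])
    if check_local_accuracy:
        recon = model.base_value + phi.sum(axis=1)
        err = np.abs(recon - predict_proba(model, X))
        if err.max() > 1e-8:
            i = int(err.argmax())
            raise AssertionError(
                f"local accuracy violated at instance {i}: |error| = {err[i]:.3g}"
            )
    names = list(model.feature_names) if model.feature_names else []
    return ExplanationMatrix(
        phi=phi,
        base_value=model.base_value,
        instance_ids=instance_ids,
        feature_names=names,
    )


def write_explanations_csv(expl: ExplanationMatrix, path) -> None:
    """CSV with an instance-id column and one column per feature; the base
    value goes to a ``<path>.meta.json`` sidecar."""
    path = Path(path)
    df = pd.DataFrame(expl.phi, columns=expl.feature_names)
    df.insert(0, "instance_id", expl.instance_ids)
    df.to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps({"base_value": expl.base_value}))


def read_explanations_csv(path) -> ExplanationMatrix:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    base = json.loads(sidecar.read_text())["base_value"]
    ids = df["instance_id"].to_numpy()
    feats = df.drop(columns=["instance_id"])
    return ExplanationMatrix(
        phi=feats.to_numpy(dtype=float),
        base_value=float(base),
        instance_ids=ids,
        feature_names=[str(c) for c in feats.columns],
    )
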