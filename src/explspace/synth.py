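"""Synthetic hypercube classification benchmark.

Generates labelled datasets in the Madelon family: each class occupies one
Gaussian cluster centred on a distinct vertex of a hypercube living in the
subspace of informative features.  Redundant features are fixed random linear
combinations of the informative ones; the remaining features are pure
standard-Gaussian noise carrying no class signal.  This reproduces the regime
in which raw Euclidean distance is dominated by noise while the class
structure is perfectly recoverable from a low-dimensional subspace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticSpec",
    "LabeledDataset",
    "generate_hypercube_dataset",
    "write_dataset_csv",
    "read_dataset_csv",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the hypercube generator.

    ``class_sep`` is the half-edge of the hypercube: vertices sit at
    ``+-class_sep`` in each informative coordinate.  ``within_cluster_sd`` is
    the isotropic Gaussian noise added around each class vertex.

    The defaults put the class signal well below the unit variance of the
    pure-noise features (so raw Euclidean geometry, and with it clustering in
    feature space, is noise-dominated) while keeping the within-cluster
    spread a third of the hypercube half-edge, so the binary diagnostic task
    stays reliably learnable by axis-aligned splits.  This is the regime in
    which subclass structure is nearly invisible in feature space yet sharply
    expressed in the classifier's explanation space.
    """

    n_samples: int = 1600
    n_classes: int = 16
    n_features: int = 50
    n_informative: int = 4
    n_redundant: int = 4
    class_sep: float = 0.3
    within_cluster_sd: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1 or self.n_classes < 1 or self.n_features < 1:
            raise ValueError("n_samples, n_classes and n_features must be positive")
        if self.n_informative < 1:
            raise ValueError("n_informative must be positive")
        if self.n_redundant < 0:
            raise ValueError("n_redundant must be non-negative")
        if self.class_sep <= 0 or self.within_cluster_sd < 0:
            raise ValueError("class_sep must be positive, within_cluster_sd non-negative")
        if 2**self.n_informative < self.n_classes:
            raise ValueError(
                f"2^n_informative = {2**self.n_informative} vertices cannot host "
                f"{self.n_classes} distinct classes"
            )
        if self.n_informative + self.n_redundant > self.n_features:
            raise ValueError(
                "n_informative + n_redundant exceeds n_features "
                f"({self.n_informative} + {self.n_redundant} > {self.n_features})"
            )


@dataclass
class LabeledDataset:
    """Feature matrix with per-row subclass labels.

    ``feature_names`` records the column identities after the generator's
    random column permutation (``inf*`` informative, ``red*`` redundant,
    ``noise*`` pure noise) or the CSV header for data read from disk.
    """

    X: np.ndarray
    y_subclass: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y_subclass = np.asarray(self.y_subclass)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if self.X.shape[0] != self.y_subclass.shape[0]:
            raise ValueError("row count of X must equal length of y_subclass")
        if np.isnan(self.X).any():
            raise ValueError("X contains missing values")
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(self.X.shape[1])]
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length must match the number of columns")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def informative_columns(self) -> list[int]:
        """Column indices of informative features (generator provenance)."""
        return [j for j, n in enumerate(self.feature_names) if n.startswith("inf")]

    def noise_columns(self) -> list[int]:
        """Column indices of pure-noise features (generator provenance)."""
        return [j for j, n in enumerate(self.feature_names) if n.startswith("noise")]


def _class_vertices(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Assign each class a distinct hypercube vertex.

    Vertices are enumerated in binary-counting order over the informative
    coordinates and then shuffled under the spec seed, so the class-to-vertex
    map is reproducible but not systematically ordered.
    """
    m = spec.n_informative
    codes = np.arange(2**m, dtype=np.int64)
    bits = (codes[:, None] >> np.arange(m)[None, :]) & 1
    vertices = np.where(bits == 1, spec.class_sep, -spec.class_sep).astype(float)
    order = rng.permutation(2**m)
    return vertices[order[: spec.n_classes]]


def generate_hypercube_dataset(spec: SyntheticSpec) -> LabeledDataset:
    """Generate one cluster per class on the vertices of a hypercube.

    Class sizes are as equal as integer division allows (the first
    ``n_samples mod n_classes`` classes get one extra instance).  The column
    order is randomly permuted under the seed; the permutation is recorded in
    ``feature_names``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    vertices = _class_vertices(spec, rng)

    base, extra = divmod(spec.n_samples, spec.n_classes)
    counts = np.full(spec.n_classes, base, dtype=int)
    counts[:extra] += 1
    y = np.repeat(np.arange(spec.n_classes), counts)

    informative = vertices[y] + spec.within_cluster_sd * rng.standard_normal(
        (spec.n_samples, spec.n_informative)
    )

    mix = rng.standard_normal((spec.n_informative, spec.n_redundant))
    redundant = informative @ mix

    n_noise = spec.n_features - spec.n_informative - spec.n_redundant
    noise = rng.standard_normal((spec.n_samples, n_noise))

    X = np.hstack([informative, redundant, noise])
    names = (
        [f"inf{j}" for j in range(spec.n_informative)]
        + [f"red{j}" for j in range(spec.n_redundant)]
        + [f"noise{j}" for j in range(n_noise)]
    )
    perm = rng.permutation(spec.n_features)
    X = X[:, perm]
    names = [names[j] for j in perm]
    return LabeledDataset(X=X, y_subclass=y, feature_names=names)


def write_dataset_csv(data: LabeledDataset, path, label_col: str = "label") -> None:
    """Write a dataset as CSV: one label column plus one column per feature."""
    df = pd.DataFrame(data.X, columns=data.feature_names)
    df.insert(0, label_col, data.y_subclass)
    df.to_csv(path, index=False)


def read_dataset_csv(path, label_col: str = "label") -> LabeledDataset:
    """Read a labelled feature table (CSV/TSV autodetected by pandas)."""
    df = pd.read_csv(path, sep=None, engine="python")
    if label_col not in df.columns:
        raise ValueError(f"label column {label_col!r} not found in {path}")
    y = df[label_col].to_numpy()
    feats = df.drop(columns=[label_col])
    return LabeledDataset(
        X=feats.to_numpy(dtype=float),
        y_subclass=y,
        feature_names=[str(c) for c in feats.columns],
    )
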