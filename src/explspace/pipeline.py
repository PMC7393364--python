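"""End-to-end subtype-discovery protocol.

The multi-class labels are collapsed into a binary superset problem (the
observable diagnosis); a random forest is trained on it; every instance is
mapped into explanation space by Shapley attribution; then both the raw
feature space and the explanation space are embedded, clustered and scored,
producing a grid of cluster-validity indices and subclass-recovery AMI per
(space, reducer) combination.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .cluster_metrics import (
    MetricGridCell,
    adjusted_mutual_information,
    calinski_harabasz,
    davies_bouldin,
    grid_to_long_csv,
    grid_to_wide_csv,
    silhouette,
)
from .embed import REDUCERS, reduce, ward_agglomerative, write_embedding_csv
from .forest import TreeEnsemble, train_random_forest
from .shapley import explain_matrix
from .synth import LabeledDataset

logger = logging.getLogger("explspace")

__all__ = [
    "ProtocolConfig",
    "BenchmarkReport",
    "split_supersets",
    "inverse_frequency_weights",
    "run_benchmark",
    "write_report",
]


@dataclass
class ProtocolConfig:
    """Settings of one benchmark run.

    ``superset_a`` is the set of subclass labels forming the positive class
    of the binary task (the 'diseased' superset); evaluation is restricted to
    its instances unless ``evaluate_all`` is set.  ``k_clusters="auto"``
    uses the number of ground-truth subclasses in the evaluated set.
    """

    superset_a: tuple = (0, 1, 2)
    balance: str = "none"  # "none" | "inverse_frequency"
    reducers: tuple = REDUCERS
    k_clusters: int | str = "auto"
    seeds: tuple = (0, 1, 2)
    n_trees: int = 100
    mtry: int | None = None
    min_leaf: int = 1
    max_depth: int | None = None
    evaluate_all: bool = False
    holdout: float | None = None  # fraction of rows kept out of forest training
    indices_against: str = "truth"  # "truth" | "clustering"

    def validate(self, y_subclass: np.ndarray) -> None:
        observed = set(np.unique(y_subclass).tolist())
        chosen = set(self.superset_a)
        if not chosen:
            raise ValueError("superset_a must be non-empty")
        missing = chosen - observed
        if missing:
            raise ValueError(f"superset_a labels never observed: {sorted(missing)}")
        if chosen == observed:
            raise ValueError("superset_a must be a strict subset of observed labels")
        if self.balance not in ("none", "inverse_frequency"):
            raise ValueError("balance must be 'none' or 'inverse_frequency'")
        unknown = set(self.reducers) - set(REDUCERS)
        if unknown:
            raise ValueError(f"unknown reducers: {sorted(unknown)}")
        if self.indices_against not in ("truth", "clustering"):
            raise ValueError("indices_against must be 'truth' or 'clustering'")


@dataclass
class BenchmarkReport:
    """Aggregated metric grid plus per-seed replicates and provenance."""

    cells: list[MetricGridCell]
    per_seed: dict  # seed -> list[MetricGridCell]
    provenance: dict = field(default_factory=dict)

    def cell(self, space: str, reducer: str) -> MetricGridCell:
        for c in self.cells:
            if c.space == space and c.reducer == reducer:
                return c
        raise KeyError((space, reducer))


def split_supersets(y_subclass: np.ndarray, superset_a) -> np.ndarray:
    """Binary labels: 1 iff the instance's subclass belongs to superset A."""
    y = np.asarray(y_subclass)
    chosen = set(superset_a)
    observed = set(np.unique(y).tolist())
    if not chosen:
        raise ValueError("superset_a must be non-empty")
    missing = chosen - observed
    if missing:
        raise ValueError(f"superset_a labels never observed: {sorted(missing)}")
    if chosen == observed:
        raise ValueError("superset_a must not contain every observed label")
    return np.isin(y, list(chosen)).astype(int)


def inverse_frequency_weights(y_binary: np.ndarray) -> np.ndarray:
    """Per-instance weights proportional to 1/count(class), normalised so the
    two class totals are equal and the weights sum to n."""
    y = np.asarray(y_binary)
    n = y.shape[0]
    n1 = int(y.sum())
    n0 = n - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present")
    w = np.where(y == 1, n / (2 * n1), n / (2 * n0))
    return w


def _dataset_fingerprint(data: LabeledDataset) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(data.X).tobytes())
    h.update(np.ascontiguousarray(data.y_subclass).tobytes())
    return h.hexdigest()[:16]


def _evaluate_grid(
    X_eval: np.ndarray,
    phi_eval: np.ndarray,
    y_eval: np.ndarray,
    reducers,
    k: int,
    seed: int,
    indices_against: str,
    collect_embeddings: dict | None = None,
) -> list[MetricGridCell]:
    cells = []
    for reducer in reducers:
        for space, M in (("feature", X_eval), ("explanation", phi_eval)):
            t0 = time.perf_counter()
            emb = reduce(M, method=reducer, seed=seed)
            part = ward_agglomerative(emb.coords, k)
            index_labels = y_eval if indices_against == "truth" else part.labels
            cell = MetricGridCell(
                space=space,
                reducer=reducer,
                davies_bouldin=davies_bouldin(emb.coords, index_labels),
                calinski_harabasz=calinski_harabasz(emb.coords, index_labels),
                silhouette=silhouette(emb.coords, index_labels),
                adjusted_mi=adjusted_mutual_information(y_eval, part.labels),
            )
            cells.append(cell)
            if collect_embeddings is not None:
                collect_embeddings[(space, reducer)] = emb
            logger.info(
                "space=%s reducer=%s done in %.2fs (DB=%.3f CH=%.1f Sil=%.3f AMI=%.3f)",
                space,
                reducer,
                time.perf_counter() - t0,
                cell.davies_bouldin,
                cell.calinski_harabasz,
                cell.silhouette,
                cell.adjusted_mi,
            )
    return cells


def run_benchmark(
    data: LabeledDataset,
    config: ProtocolConfig,
    collect_embeddings: dict | None = None,
    return_models: dict | None = None,
) -> BenchmarkReport:
    """Run the full protocol for every configured seed and average the grid.

    Per seed: binary superset labels -> (optional) balance weights -> forest
    -> explanation matrix -> restrict to the evaluated instances -> for each
    (space, reducer): embed, Ward-cluster, score.  The master seed fans out
    into independent forest/reducer streams.
    """
    config.validate(data.y_subclass)
    y_bin = split_supersets(data.y_subclass, config.superset_a)
    weights = (
        inverse_frequency_weights(y_bin) if config.balance == "inverse_frequency" else None
    )
    eval_mask = (
        np.ones(data.n_samples, dtype=bool) if config.evaluate_all else y_bin == 1
    )
    y_eval = data.y_subclass[eval_mask]
    k = (
        int(len(np.unique(y_eval)))
        if config.k_clusters == "auto"
        else int(config.k_clusters)
    )
    if eval_mask.sum() < k:
        raise ValueError(
            f"fewer evaluated instances ({int(eval_mask.sum())}) than clusters ({k})"
        )

    per_seed: dict[int, list[MetricGridCell]] = {}
    for seed in config.seeds:
        t0 = time.perf_counter()
        forest_seed, reducer_seed = (
            int(s.generate_state(1)[0] >> 1)
            for s in np.random.SeedSequence(seed).spawn(2)
        )
        train_mask = np.ones(data.n_samples, dtype=bool)
        if config.holdout is not None:
            rng = np.random.default_rng(forest_seed)
            n_hold = int(round(config.holdout * data.n_samples))
            train_mask[rng.choice(data.n_samples, size=n_hold, replace=False)] = False
        model = train_random_forest(
            data.X[train_mask],
            y_bin[train_mask],
            n_trees=config.n_trees,
            mtry=config.mtry,
            min_leaf=config.min_leaf,
            max_depth=config.max_depth,
            sample_weights=None if weights is None else weights[train_mask],
            seed=forest_seed,
        )
        model.feature_names = list(data.feature_names)
        logger.info(
            "seed=%d forest trained in %.2fs (%d trees)",
            seed,
            time.perf_counter() - t0,
            model.n_trees,
        )
        if return_models is not None:
            return_models[seed] = model
        t1 = time.perf_counter()
        expl = explain_matrix(model, data.X)
        logger.info(
            "seed=%d explanations computed in %.2fs", seed, time.perf_counter() - t1
        )
        per_seed[seed] = _evaluate_grid(
            data.X[eval_mask],
            expl.phi[eval_mask],
            y_eval,
            config.reducers,
            k,
            reducer_seed,
            config.indices_against,
            collect_embeddings if seed == config.seeds[0] else None,
        )
        logger.info("seed=%d finished in %.2fs", seed, time.perf_counter() - t0)

    cells = []
    first = per_seed[config.seeds[0]]
    for i, proto in enumerate(first):
        cells.append(
            MetricGridCell(
                space=proto.space,
                reducer=proto.reducer,
                davies_bouldin=float(
                    np.mean([per_seed[s][i].davies_bouldin for s in config.seeds])
                ),
                calinski_harabasz=float(
                    np.mean([per_seed[s][i].calinski_harabasz for s in config.seeds])
                ),
                silhouette=float(
                    np.mean([per_seed[s][i].silhouette for s in config.seeds])
                ),
                adjusted_mi=float(
                    np.mean([per_seed[s][i].adjusted_mi for s in config.seeds])
                ),
            )
        )
    provenance = {
        "config": {
            "superset_a": [
                x.item() if hasattr(x, "item") else x for x in config.superset_a
            ],
            "balance": config.balance,
            "reducers": list(config.reducers),
            "k_clusters": k,
            "seeds": list(config.seeds),
            "n_trees": config.n_trees,
            "mtry": config.mtry,
            "min_leaf": config.min_leaf,
            "max_depth": config.max_depth,
            "evaluate_all": config.evaluate_all,
            "holdout": config.holdout,
            "indices_against": config.indices_against,
        },
        "dataset_fingerprint": _dataset_fingerprint(data),
        "n_samples": int(data.n_samples),
        "n_features": int(data.n_features),
        "version": __version__,
    }
    return BenchmarkReport(cells=cells, per_seed=per_seed, provenance=provenance)


def write_report(report: BenchmarkReport, outdir, dataset: str = "synthetic") -> None:
    """JSON report plus long/wide CSV metric tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    doc = {
        "provenance": report.provenance,
        "grid": [
            {
                "space": c.space,
                "reducer": c.reducer,
                "davies_bouldin": c.davies_bouldin,
                "calinski_harabasz": c.calinski_harabasz,
                "silhouette": c.silhouette,
                "adjusted_mi": c.adjusted_mi,
            }
            for c in report.cells
        ],
        "per_seed": {
            str(seed): [
                {
                    "space": c.space,
                    "reducer": c.reducer,
                    "davies_bouldin": c.davies_bouldin,
                    "calinski_harabasz": c.calinski_harabasz,
                    "silhouette": c.silhouette,
                    "adjusted_mi": c.adjusted_mi,
                }
                for c in cells
            ]
            for seed, cells in report.per_seed.items()
        },
    }
    (outdir / "report.json").write_text(json.dumps(doc, indent=2))
    grid_to_long_csv(report.cells, outdir / "metrics_long.csv", dataset=dataset)
    grid_to_wide_csv(report.cells, outdir / "metrics_wide.csv", dataset=dataset)
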