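"""Validity indices and AMI: hand-computed values, invariances, oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import (
    adjusted_mutual_info_score,
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from explspace.cluster_metrics import (
    MetricGridCell,
    adjusted_mutual_information,
    calinski_harabasz,
    davies_bouldin,
    silhouette,
)

TWO_PAIRS_NEAR = np.array([[0.0], [0.1], [10.0], [10.1]])
TWO_PAIRS_UNIT = np.array([[0.0], [1.0], [10.0], [11.0]])
PAIR_LABELS = np.array([0, 0, 1, 1])


class TestHandComputedValues:
    def test_davies_bouldin_two_tight_pairs(self):
        # s = 0.05 per cluster, centroid gap 10 -> DB = 0.01
        assert davies_bouldin(TWO_PAIRS_NEAR, PAIR_LABELS) == pytest.approx(0.01)

    def test_calinski_harabasz_two_unit_pairs(self):
        # B = 100, W = 1, n = 4, k = 2 -> (100/1)/(1/2) = 200
        assert calinski_harabasz(TWO_PAIRS_UNIT, PAIR_LABELS) == pytest.approx(200.0)

    def test_silhouette_two_unit_pairs(self):
        # per point: 9.5/10.5, 8.5/9.5, 8.5/9.5, 9.5/10.5 -> mean 0.89975
        expected = (2 * (9.5 / 10.5) + 2 * (8.5 / 9.5)) / 4
        assert expected == pytest.approx(0.8997, abs=5e-5)
        assert silhouette(TWO_PAIRS_UNIT, PAIR_LABELS) == pytest.approx(expected)

    def test_singleton_clusters_have_zero_dispersion(self):
        X = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 4.0]])
        assert davies_bouldin(X, np.array([0, 1, 2])) == 0.0

    def test_identical_centroids_with_dispersion_rejected(self):
        X = np.array([[-1.0], [1.0], [-1.0], [1.0]])
        with pytest.raises(ZeroDivisionError, match="centroid"):
            davies_bouldin(X, np.array([0, 0, 1, 1]))

    def test_zero_within_dispersion_is_infinite_ch(self):
        X = np.array([[0.0], [0.0], [5.0], [5.0]])
        assert calinski_harabasz(X, PAIR_LABELS) == np.inf

    def test_coincident_clusters_nonpositive_silhouette(self):
        # identical point sets {0, 1} assigned to both clusters
        X = np.array([[0.0], [1.0], [0.0], [1.0]])
        assert silhouette(X, np.array([0, 0, 1, 1])) <= 0.0


@pytest.fixture(scope="module")
def blobs():
    rng = np.random.default_rng(6)
    X = np.concatenate([rng.standard_normal((30, 3)) + 4 * v for v in np.eye(3)])
    labels = np.repeat(np.arange(3), 30)
    return X, labels


class TestInvariances:

    def test_label_renaming_invariance(self, blobs):
        X, labels = blobs
        renamed = (labels + 1) % 3
        for fn in (davies_bouldin, calinski_harabasz, silhouette):
            assert fn(X, labels) == pytest.approx(fn(X, renamed))
        assert adjusted_mutual_information(labels, renamed) == pytest.approx(1.0)

    def test_row_reordering_invariance(self, blobs):
        X, labels = blobs
        perm = np.random.default_rng(7).permutation(len(labels))
        for fn in (davies_bouldin, calinski_harabasz, silhouette):
            assert fn(X[perm], labels[perm]) == pytest.approx(fn(X, labels))

    def test_ch_translation_and_scale_invariance(self, blobs):
        X, labels = blobs
        base = calinski_harabasz(X, labels)
        assert calinski_harabasz(X + 13.7, labels) == pytest.approx(base)
        assert calinski_harabasz(X * 3.1, labels) == pytest.approx(base)

    def test_separation_sweep_monotonicity(self):
        rng = np.random.default_rng(8)
        noise = rng.standard_normal((80, 2))
        labels = np.repeat([0, 1], 40)
        db_vals, ch_vals, sil_vals = [], [], []
        for sep in (2.0, 4.0, 8.0, 16.0):
            X = noise + np.outer(labels, [sep, 0.0])
            db_vals.append(davies_bouldin(X, labels))
            ch_vals.append(calinski_harabasz(X, labels))
            sil_vals.append(silhouette(X, labels))
        assert all(a > b for a, b in zip(db_vals, db_vals[1:]))
        assert all(a < b for a, b in zip(ch_vals, ch_vals[1:]))
        assert all(a < b for a, b in zip(sil_vals, sil_vals[1:]))


class TestAgainstStandardImplementations:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_indices_match_sklearn_on_random_data(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((50, 4))
        labels = rng.integers(0, 3, size=50)
        assert davies_bouldin(X, labels) == pytest.approx(
            davies_bouldin_score(X, labels)
        )
        assert calinski_harabasz(X, labels) == pytest.approx(
            calinski_harabasz_score(X, labels)
        )
        assert silhouette(X, labels) == pytest.approx(silhouette_score(X, labels))
        other = rng.integers(0, 4, size=50)
        assert adjusted_mutual_information(labels, other) == pytest.approx(
            adjusted_mutual_info_score(labels, other), abs=1e-9
        )


class TestAdjustedMutualInformation:
    def test_identical_partitions_score_one(self):
        labels = np.array([0, 0, 1, 1, 2, 2, 2])
        assert adjusted_mutual_information(labels, labels) == 1.0

    def test_single_cluster_scores_zero(self):
        truth = np.array([0, 0, 1, 1, 2, 2])
        assert adjusted_mutual_information(truth, np.zeros(6)) == pytest.approx(0.0)

    def test_symmetry(self, rng):
        a = rng.integers(0, 3, 40)
        b = rng.integers(0, 5, 40)
        assert adjusted_mutual_information(a, b) == pytest.approx(
            adjusted_mutual_information(b, a)
        )

    def test_exact_emi_matches_exhaustive_permutation_oracle(self):
        a = np.array([0, 0, 1, 1, 2, 2])
        b = np.array([0, 0, 1, 2, 2, 1])
        # enumerate every class-size-preserving relabeling of b
        perms = {p for p in itertools.permutations(b.tolist())}
        mis = []
        for p in perms:
            p = np.array(p)
            table = np.zeros((3, 3))
            np.add.at(table, (a, p), 1)
            n = 6
            mi = 0.0
            for i in range(3):
                for j in range(3):
                    nij = table[i, j]
                    if nij:
                        mi += nij / n * np.log(n * nij / (table[i].sum() * table[:, j].sum()))
            mis.append(mi)
        emi = float(np.mean(mis))
        # recompute AMI with the enumerated E[MI] and compare to ours
        table = np.zeros((3, 3))
        np.add.at(table, (a, b), 1)
        n = 6
        mi = sum(
            table[i, j] / n * np.log(n * table[i, j] / (table[i].sum() * table[:, j].sum()))
            for i in range(3)
            for j in range(3)
            if table[i, j]
        )
        h = -sum(2 / 6 * np.log(2 / 6) for _ in range(3))
        expected = (mi - emi) / (h - emi)
        assert adjusted_mutual_information(a, b) == pytest.approx(expected, abs=1e-12)

    def test_max_normalizer_flag(self, rng):
        a = rng.integers(0, 3, 30)
        b = rng.integers(0, 5, 30)
        ours = adjusted_mutual_information(a, b, normalizer="max")
        ref = adjusted_mutual_info_score(a, b, average_method="max")
        assert ours == pytest.approx(ref, abs=1e-9)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="equal length"):
            adjusted_mutual_information(np.zeros(3), np.zeros(4))

    @given(st.integers(0, 1000))
    def test_bounded_above_by_one(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 4, 20)
        b = rng.integers(0, 4, 20)
        assert adjusted_mutual_information(a, b) <= 1.0 + 1e-12


def test_metric_grid_cell_accessor():
    cell = MetricGridCell("feature", "pca", 1.0, 2.0, 0.3, 0.4)
    assert cell.metric("davies_bouldin") == 1.0
    assert cell.metric("adjusted_mi") == 0.4
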