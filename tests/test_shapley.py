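"""Shapley attribution: conditional expectations, axioms, oracle agreement."""

import numpy as np
import pytest

from explspace.forest import TreeEnsemble, TreeModel, predict_proba, train_random_forest
from explspace.shapley import (
    brute_force_shap,
    explain_matrix,
    read_explanations_csv,
    tree_expected_value,
    tree_shap,
    write_explanations_csv,
)

from _oracles import enumerate_tree_expectation, random_small_forest


def stump(left_value=0.2, right_value=0.8, left_cover=50.0, right_cover=50.0):
    cover = left_cover + right_cover
    root = (left_cover * left_value + right_cover * right_value) / cover
    return TreeModel(
        children_left=[1, -1, -1],
        children_right=[2, -1, -1],
        split_feature=[0, -2, -2],
        split_threshold=[0.0, np.nan, np.nan],
        leaf_value=[root, left_value, right_value],
        node_cover=[cover, left_cover, right_cover],
    )


def and_tree():
    """Output 1 iff both features positive; symmetric in the two features."""
    return TreeModel(
        children_left=[1, -1, 3, -1, -1],
        children_right=[2, -1, 4, -1, -1],
        split_feature=[0, -2, 1, -2, -2],
        split_threshold=[0.0, np.nan, 0.0, np.nan, np.nan],
        leaf_value=[0.25, 0.0, 0.5, 0.0, 1.0],
        node_cover=[100.0, 50.0, 50.0, 25.0, 25.0],
    )


class TestTreeExpectedValue:
    def test_full_conditioning_routes_like_prediction(self, rng):
        model, p = random_small_forest(rng)
        tree = model.trees[0]
        x = rng.standard_normal(p)
        assert tree_expected_value(tree, x, set(range(p))) == pytest.approx(
            float(tree.decision_path_values(x[None, :])[0])
        )

    def test_empty_subset_is_cover_weighted_mean(self):
        assert tree_expected_value(stump(), np.array([5.0]), set()) == 0.5
        assert tree_expected_value(
            stump(left_cover=75.0, right_cover=25.0), np.array([5.0]), set()
        ) == pytest.approx(0.75 * 0.2 + 0.25 * 0.8)

    def test_matches_leaf_enumeration_oracle(self, rng):
        for _ in range(20):
            model, p = random_small_forest(rng, max_depth=3)
            tree = model.trees[0]
            x = rng.standard_normal(p)
            known = {0} if p == 1 else set(
                rng.choice(p, size=rng.integers(0, p + 1), replace=False).tolist()
            )
            assert tree_expected_value(tree, x, known) == pytest.approx(
                enumerate_tree_expectation(tree, x, known), abs=1e-12
            )


class TestBruteForce:
    def test_stump_gives_whole_surplus_to_single_feature(self):
        model = TreeEnsemble(trees=[stump()], n_features=1, base_value=0.5)
        phi = brute_force_shap(model, np.array([1.0]))
        assert phi == pytest.approx([0.3])

    def test_symmetric_features_get_equal_credit(self):
        model = TreeEnsemble(trees=[and_tree()], n_features=2, base_value=0.25)
        phi = brute_force_shap(model, np.array([1.0, 1.0]))
        assert phi[0] == pytest.approx(phi[1])
        assert phi.sum() == pytest.approx(1.0 - 0.25)

    def test_efficiency_axiom(self, rng):
        for _ in range(5):
            model, p = random_small_forest(rng)
            x = rng.standard_normal(p)
            phi = brute_force_shap(model, x)
            v_empty = float(np.mean([t.leaf_value[0] for t in model.trees]))
            assert v_empty + phi.sum() == pytest.approx(
                float(predict_proba(model, x[None, :])[0]), abs=1e-10
            )

    def test_exponential_guard(self):
        model = TreeEnsemble(trees=[stump()], n_features=13, base_value=0.5)
        with pytest.raises(ValueError, match="exponential"):
            brute_force_shap(model, np.zeros(13))


class TestTreeShap:
    def test_stump_closed_form(self):
        model = TreeEnsemble(trees=[stump()], n_features=1, base_value=0.5)
        assert tree_shap(model, np.array([1.0])) == pytest.approx([0.3])
        assert tree_shap(model, np.array([-1.0])) == pytest.approx([-0.3])

    def test_matches_brute_force_on_random_forests(self, rng):
        worst = 0.0
        for _ in range(10):
            model, p = random_small_forest(rng)
            for _ in range(5):
                x = rng.standard_normal(p)
                diff = np.abs(tree_shap(model, x) - brute_force_shap(model, x)).max()
                worst = max(worst, diff)
        assert worst < 1e-8

    def test_unused_feature_gets_exactly_zero(self, rng):
        # forest over 5 features whose trees only ever split features 0..2
        X = rng.standard_normal((60, 3))
        y = (X[:, 0] + X[:, 1] > 0).astype(int)
        small = train_random_forest(X, y, n_trees=5, max_depth=3, seed=0)
        padded_trees = [
            TreeModel(t.children_left, t.children_right, t.split_feature,
                      t.split_threshold, t.leaf_value, t.node_cover)
            for t in small.trees
        ]
        model = TreeEnsemble(trees=padded_trees, n_features=5,
                             base_value=small.base_value)
        phi = tree_shap(model, rng.standard_normal(5))
        assert phi[3] == 0.0 and phi[4] == 0.0

    def test_additivity_across_trees(self, rng):
        m1, p = random_small_forest(rng, n_features=4, n_trees=1)
        m2, _ = random_small_forest(rng, n_features=4, n_trees=1)
        both = TreeEnsemble(
            trees=m1.trees + m2.trees,
            n_features=4,
            base_value=(m1.base_value + m2.base_value) / 2,
        )
        x = rng.standard_normal(4)
        assert tree_shap(both, x) == pytest.approx(
            (tree_shap(m1, x) + tree_shap(m2, x)) / 2, abs=1e-12
        )

    def test_constant_model_attributes_nothing(self):
        leaf = TreeModel([-1], [-1], [-2], [np.nan], [0.6], [40.0])
        model = TreeEnsemble(trees=[leaf, leaf], n_features=3, base_value=0.6)
        assert (tree_shap(model, np.array([1.0, -2.0, 0.5])) == 0.0).all()


class TestExplainMatrix:
    def test_single_row_equals_tree_shap(self, rng):
        model, p = random_small_forest(rng)
        x = rng.standard_normal(p)
        expl = explain_matrix(model, x[None, :])
        assert expl.phi.shape == (1, p)
        assert np.allclose(expl.phi[0], tree_shap(model, x))

    def test_local_accuracy_holds_rowwise(self, rng):
        model, p = random_small_forest(rng, n_trees=8)
        X = rng.standard_normal((30, p))
        expl = explain_matrix(model, X)  # raises internally if violated
        recon = expl.base_value + expl.phi.sum(axis=1)
        assert np.abs(recon - predict_proba(model, X)).max() < 1e-8

    def test_explanation_keeps_feature_dimensionality(
        self, default_explanations, default_dataset
    ):
        assert default_explanations.phi.shape == (
            default_dataset.n_samples,
            default_dataset.n_features,
        )

    def test_noise_features_attributed_far_less_than_informative(
        self, default_explanations, default_dataset
    ):
        phi = default_explanations.phi
        inf = np.abs(phi[:, default_dataset.informative_columns()]).mean()
        noise = np.abs(phi[:, default_dataset.noise_columns()]).mean()
        assert inf > 10 * noise

    def test_csv_round_trip(self, tmp_path, rng):
        model, p = random_small_forest(rng)
        expl = explain_matrix(model, rng.standard_normal((6, p)))
        path = tmp_path / "phi.csv"
        write_explanations_csv(expl, path)
        back = read_explanations_csv(path)
        assert np.allclose(back.phi, expl.phi)
        assert back.base_value == pytest.approx(expl.base_value)
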