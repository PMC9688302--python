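"""Shapley decomposition: oracle examples, axioms, and engine equivalence."""

import numpy as np
import pytest

import voxelage as va
from voxelage.shapley import (
    SetFunction,
    cohort_shap,
    shapley_interactions_exact,
    shapley_interactions_tree,
    shapley_values_exact,
    shapley_values_tree,
    tree_expectation,
    tree_set_function,
)

from conftest import make_stump, random_ensemble


def game_from_table(table: dict, m: int) -> SetFunction:
    return SetFunction(m=m, evaluate=lambda S, x: table[frozenset(S)])


TWO_FEATURE_GAME = game_from_table(
    {frozenset(): 0.0, frozenset({0}): 1.0, frozenset({1}): 2.0, frozenset({0, 1}): 4.0}, m=2
)


class TestTreeExpectation:
    def test_known_feature_follows_branch(self):
        model = make_stump()
        assert tree_expectation(model, {0}, np.array([0.7, 0.0])) == 3.0
        assert tree_expectation(model, {0}, np.array([0.2, 0.0])) == 1.0

    def test_empty_set_is_cover_weighted_mean(self):
        model = make_stump(cover_left=50, cover_right=50)
        assert tree_expectation(model, set(), np.array([0.7, 0.0])) == 2.0
        skew = make_stump(cover_left=75, cover_right=25)
        assert tree_expectation(skew, set(), np.zeros(2)) == 0.75 * 1 + 0.25 * 3

    def test_full_set_equals_prediction(self):
        model = random_ensemble(0)
        rng = np.random.default_rng(1)
        for x in rng.uniform(size=(20, model.n_features)):
            f_full = tree_expectation(model, range(model.n_features), x)
            assert f_full == pytest.approx(va.predict(model, x)[0], abs=1e-12)

    def test_zero_cover_raises(self):
        from voxelage.model import EnsembleModel, TreeNode

        bad = TreeNode(
            cover=1.0,
            feature=0,
            threshold=0.5,
            left=TreeNode(cover=0.0, leaf_value=1.0),
            right=TreeNode(cover=0.0, leaf_value=2.0),
        )
        model = EnsembleModel(trees=[bad], base_score=0.0, n_features=1)
        with pytest.raises(ValueError, match="cover"):
            tree_expectation(model, set(), np.zeros(1))


class TestExactOracle:
    def test_worked_two_feature_game(self):
        dec = shapley_values_exact(TWO_FEATURE_GAME)
        assert dec.phi0 == 0.0
        np.testing.assert_allclose(dec.phi, [1.5, 2.5])
        it = shapley_interactions_exact(TWO_FEATURE_GAME)
        np.testing.assert_allclose(it.values, [[1.0, 0.5], [0.5, 2.0]])
        assert it.values.sum() == pytest.approx(dec.prediction - dec.phi0)

    def test_additive_game_recovers_coefficients(self):
        c = np.array([3.0, -1.0, 0.5])
        sf = SetFunction(m=3, evaluate=lambda S, x: sum(c[i] for i in S))
        dec = shapley_values_exact(sf)
        np.testing.assert_allclose(dec.phi, c, atol=1e-12)
        it = shapley_interactions_exact(sf)
        off = it.values - np.diag(np.diag(it.values))
        np.testing.assert_allclose(off, 0.0, atol=1e-12)
        np.testing.assert_allclose(np.diag(it.values), c, atol=1e-12)

    def test_symmetry_axiom_for_interchangeable_features(self):
        sf = SetFunction(m=2, evaluate=lambda S, x: float(len(S)) ** 2)
        dec = shapley_values_exact(sf)
        assert dec.phi[0] == pytest.approx(dec.phi[1])

    def test_pure_product_game_interaction(self):
        """f = x1*x2 only when both features present, at x1 = x2 = 1."""
        sf = SetFunction(m=2, evaluate=lambda S, x: 1.0 if S == frozenset({0, 1}) else 0.0)
        it = shapley_interactions_exact(sf)
        assert it.values[0, 1] + it.values[1, 0] == pytest.approx(1.0)
        assert it.values[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert it.values[1, 1] == pytest.approx(0.0, abs=1e-12)

    def test_cap_exceeded_directs_to_tree_engine(self):
        sf = SetFunction(m=20, evaluate=lambda S, x: 0.0)
        with pytest.raises(ValueError, match="tree engine"):
            shapley_values_exact(sf)


class TestTreeEngineEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_ensembles(self, seed):
        model = random_ensemble(seed, n_features=8, n_trees=8, depth=3)
        sf = tree_set_function(model)
        rng = np.random.default_rng(seed + 100)
        for x in rng.uniform(size=(2, 8)):
            bf_v = shapley_values_exact(sf, x)
            tr_v = shapley_values_tree(model, x)
            assert abs(bf_v.phi0 - tr_v.phi0) < 1e-9
            np.testing.assert_allclose(bf_v.phi, tr_v.phi, atol=1e-9)
            bf_i = shapley_interactions_exact(sf, x)
            tr_i = shapley_interactions_tree(model, x)
            np.testing.assert_allclose(bf_i.values, tr_i.values, atol=1e-9)

    def test_stump_examples_through_tree_engine(self):
        model = make_stump()
        dec = shapley_values_tree(model, np.array([0.7, 0.0]))
        assert dec.phi0 == pytest.approx(2.0)
        np.testing.assert_allclose(dec.phi, [1.0, 0.0], atol=1e-12)

    def test_dummy_feature_has_zero_everything(self):
        model = random_ensemble(3, n_features=6, n_trees=6, depth=2)
        # feature 5 is likely used; force an extra dummy column instead
        model.n_features = 7
        x = np.random.default_rng(0).uniform(size=7)
        dec = shapley_values_tree(model, x)
        it = shapley_interactions_tree(model, x)
        assert dec.phi[6] == 0.0
        np.testing.assert_array_equal(it.values[6, :], 0.0)
        np.testing.assert_array_equal(it.values[:, 6], 0.0)


class TestContracts:
    def test_additivity_and_completeness_on_fitted_model(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(80, 10))
        y = X @ rng.normal(size=10) + 30 + rng.normal(size=80) * 0.2
        model = va.fit(X, y, seed=0)
        decs, tensors = cohort_shap(model, X[:25])
        for d, t in zip(decs, tensors):
            assert d.additivity_residual() < 1e-8
            assert abs(t.values.sum() - (d.prediction - d.phi0)) < 1e-8
            # row identity: phi_i = phi_ii + sum_{j != i} phi_ij
            rows = t.values.sum(axis=1)
            np.testing.assert_allclose(rows, d.phi, atol=1e-10)
            np.testing.assert_allclose(t.values, t.values.T, atol=0)

    def test_batch_of_one_equals_single_call(self):
        model = random_ensemble(7)
        x = np.random.default_rng(1).uniform(size=model.n_features)
        decs, tensors = cohort_shap(model, x[None, :], ["s"])
        single_v = shapley_values_tree(model, x, "s")
        single_i = shapley_interactions_tree(model, x, "s")
        np.testing.assert_array_equal(decs[0].phi, single_v.phi)
        np.testing.assert_array_equal(tensors[0].values, single_i.values)

    def test_permuting_rows_permutes_outputs(self):
        model = random_ensemble(8)
        X = np.random.default_rng(2).uniform(size=(6, model.n_features))
        decs, _ = cohort_shap(model, X, interactions=False)
        perm = [3, 1, 5, 0, 2, 4]
        decs_p, _ = cohort_shap(model, X[perm], interactions=False)
        for i, p in enumerate(perm):
            np.testing.assert_array_equal(decs_p[i].phi, decs[p].phi)

    def test_wide_tree_rejected_with_guidance(self):
        from voxelage.model import EnsembleModel, TreeNode

        def chain(depth, feat=0):
            if depth == 0:
                return TreeNode(cover=1.0, leaf_value=0.0)
            left = chain(depth - 1, feat + 1)
            right = TreeNode(cover=left.cover, leaf_value=1.0)
            return TreeNode(
                cover=left.cover + right.cover,
                feature=feat,
                threshold=0.5,
                left=left,
                right=right,
            )

        model = EnsembleModel(trees=[chain(17)], base_score=0.0, n_features=17)
        with pytest.raises(ValueError, match="depth"):
            cohort_shap(model, np.zeros((1, 17)))
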