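import json

import numpy as np
import pytest

from rert.cart import (
    GrowParams,
    RegressionTree,
    best_split,
    cost_complexity_path,
    grow_tree,
    node_impurity,
    predict,
    prune_at_alpha,
    select_subtree_cv,
    stratified_fold_ids,
)
from rert.data_io import NOMINAL, CovariateSpec, Cohort

from .conftest import make_cohort
from .oracles import exhaustive_grow, tree_to_tuples

SMALL = GrowParams(min_split=4, min_leaf=2, cp=0.0, v_folds=2)


class TestNodeImpurity:
    @pytest.mark.parametrize(
        "members,expected",
        [([0, 0, 0, 0], 0.0), ([1, 0], 0.5), ([1, 1, 1, 0, 0], 1.2), ([1], 0.0)],
    )
    def test_equals_sum_of_squared_deviations(self, members, expected):
        assert node_impurity(members) == pytest.approx(expected, abs=1e-15)

    def test_empty_node_is_an_error(self):
        with pytest.raises(ValueError):
            node_impurity([])


class TestBestSplit:
    def test_step_function_splits_at_midpoint(self):
        X = np.arange(1, 11, dtype=float).reshape(-1, 1)
        y = (X[:, 0] >= 5).astype(int)
        rule = best_split(make_cohort(X, y), SMALL)
        assert rule.threshold == pytest.approx(4.5)
        # root impurity 10*0.6*0.4 = 2.4 and the children are pure
        assert node_impurity(y) == pytest.approx(2.4)

    def test_constant_outcome_gives_no_split(self):
        X = np.arange(10, dtype=float).reshape(-1, 1)
        assert best_split(make_cohort(X, np.zeros(10, dtype=int)), SMALL) is None

    def test_tied_covariates_resolve_to_schema_order(self):
        X0 = np.arange(1, 11, dtype=float)
        X = np.column_stack([X0, X0])  # identical columns
        y = (X0 >= 5).astype(int)
        rule = best_split(make_cohort(X, y), SMALL)
        assert rule.cov_index == 0

    def test_nominal_split_via_level_mean_ordering(self):
        # three levels with means 0.0, 1.0, 0.5 -> optimal subset {level 0}
        lv = np.array([0] * 6 + [1] * 6 + [2] * 6, dtype=float)
        y = np.array([0] * 6 + [1] * 6 + [1, 0, 1, 0, 1, 0])
        spec = [CovariateSpec("color", NOMINAL, levels=("a", "b", "c"))]
        cohort = Cohort(spec, lv.reshape(-1, 1), y, np.array(["s"] * 18, dtype=object))
        rule = best_split(cohort, SMALL)
        assert rule.form == "level-subset"
        assert rule.left_levels == frozenset({0})


class TestGrowTree:
    def test_noiseless_interaction_grid_recovered_exactly(self):
        # x1 on a grid of 20, x2 on a grid of 10; y = 1[x1 >= 78]*1[x2 < 31.5]
        x1 = np.repeat(np.linspace(40, 160, 20), 10)
        x2 = np.tile(np.linspace(20, 40, 10), 20)
        X = np.column_stack([x1, x2])
        y = ((x1 >= 78) & (x2 < 31.5)).astype(int)
        tree = grow_tree(make_cohort(X, y), GrowParams(min_split=10, min_leaf=5, cp=0.001))
        assert tree.n_leaves == 3
        cuts = {
            tree.nodes[i].split.covariate: tree.nodes[i].split.threshold
            for i in tree.internal_ids()
        }
        assert abs(cuts["x0"] - 78) <= (160 - 40) / 19 / 2 + 1e-9  # half grid spacing
        assert abs(cuts["x1"] - 31.5) <= (40 - 20) / 9 / 2 + 1e-9
        # noiseless recovery: predictions reproduce the outcome exactly
        np.testing.assert_array_equal(tree.predict_matrix(X), y)

    def test_all_positive_cohort_is_single_leaf(self):
        X = np.arange(5, dtype=float).reshape(-1, 1)
        tree = grow_tree(make_cohort(X, np.ones(5, dtype=int)), SMALL)
        assert tree.n_leaves == 1 and tree.root.yhat == 1.0

    def test_leaf_yhat_is_exact_relative_frequency(self, small_signal_cohort):
        tree = grow_tree(small_signal_cohort, GrowParams(min_split=10, min_leaf=5))
        for nid in tree.leaf_ids():
            node = tree.nodes[nid]
            assert node.yhat == node.n_pos / node.n

    def test_conservation_of_positives_and_impurity(self, small_signal_cohort):
        tree = grow_tree(small_signal_cohort, GrowParams(min_split=10, min_leaf=5))
        leaves = [tree.nodes[i] for i in tree.leaf_ids()]
        assert sum(nd.n_pos for nd in leaves) == int(small_signal_cohort.y.sum())
        assert sum(nd.n for nd in leaves) == small_signal_cohort.n
        total_decrease = sum(
            tree.nodes[i].decrease for i in tree.internal_ids()
        )
        leaf_impurity = sum(nd.impurity for nd in leaves)
        assert tree.root.impurity == pytest.approx(leaf_impurity + total_decrease, rel=1e-12)

    def test_missing_values_route_with_observed_majority(self):
        X = np.array([[1.0], [2.0], [3.0], [10.0], [11.0], [12.0], [13.0], [14.0], [np.nan], [np.nan]])
        y = np.array([0, 0, 0, 1, 1, 1, 1, 1, 1, 1])
        tree = grow_tree(make_cohort(X, y), GrowParams(min_split=4, min_leaf=2, cp=0.0))
        rule = tree.root.split
        # 5 observed rows >= threshold vs 3 below -> missing go right
        assert rule.surrogate_direction == "right"
        left, right = (tree.nodes[c] for c in tree.root.children)
        assert left.n + right.n == 10

    def test_determinism_bit_for_bit(self, small_signal_cohort):
        params = GrowParams(min_split=10, min_leaf=5, seed=42)
        a = grow_tree(small_signal_cohort, params).to_json()
        b = grow_tree(small_signal_cohort, params).to_json()
        assert a == b


class TestOracleEquivalence:
    def test_grown_trees_match_exhaustive_search(self, rng):
        """Random small complete-data cohorts match the brute-force reference
        split-for-split, including tie-breaks on integer-grid covariates."""
        params = GrowParams(min_split=8, min_leaf=3, max_depth=4, cp=0.01)
        for rep in range(30):
            n = int(rng.integers(15, 51))
            p = int(rng.integers(1, 4))
            X = rng.integers(0, 8, size=(n, p)).astype(float)
            y = rng.integers(0, 2, n)
            cohort = make_cohort(X, y)
            tree = grow_tree(cohort, params)
            root_imp = node_impurity(y)
            oracle = exhaustive_grow(
                X, y, params.min_split, params.min_leaf, params.max_depth, params.cp * root_imp
            )
            assert tree_to_tuples(tree) == oracle, f"mismatch at replicate {rep}"

    def test_matches_sklearn_on_unambiguous_fixture(self, rng):
        sklearn_tree = pytest.importorskip("sklearn.tree")
        X = rng.normal(size=(80, 3))
        y = ((X[:, 0] > 0.2) & (X[:, 1] < 0.5)).astype(int)
        tree = grow_tree(make_cohort(X, y), GrowParams(min_split=10, min_leaf=5, cp=0.01))
        ref = sklearn_tree.DecisionTreeRegressor(
            min_samples_split=10, min_samples_leaf=5, ccp_alpha=0.0, random_state=0
        ).fit(X, y)
        assert tree.root.split.cov_index == int(ref.tree_.feature[0])
        assert tree.root.split.threshold == pytest.approx(float(ref.tree_.threshold[0]), rel=1e-6)


class TestComplexityPath:
    def test_single_split_tree_path(self):
        X = np.arange(1, 11, dtype=float).reshape(-1, 1)
        y = (X[:, 0] >= 5).astype(int)
        tree = grow_tree(make_cohort(X, y), GrowParams(min_split=10, min_leaf=4, cp=0.0))
        assert tree.n_leaves == 2
        path = cost_complexity_path(tree)
        assert path.alphas == pytest.approx([0.0, 2.4])
        assert [t.n_leaves for t in path.subtrees] == [2, 1]

    def test_root_only_tree_is_a_singleton_path(self):
        X = np.arange(4, dtype=float).reshape(-1, 1)
        tree = grow_tree(make_cohort(X, np.array([0, 0, 0, 0])), SMALL)
        path = cost_complexity_path(tree)
        assert path.alphas == [0.0]
        assert len(path.subtrees) == 1

    def test_path_is_strictly_nested(self, small_signal_cohort):
        tree = grow_tree(small_signal_cohort, GrowParams(min_split=10, min_leaf=5, cp=0.001))
        path = cost_complexity_path(tree)
        leaf_counts = [t.n_leaves for t in path.subtrees]
        assert all(a > b for a, b in zip(leaf_counts, leaf_counts[1:]))
        assert leaf_counts[-1] == 1
        assert all(a < b for a, b in zip(path.alphas, path.alphas[1:]))
        # nesting: every node of subtree k+1 is a node of subtree k
        for prev, nxt in zip(path.subtrees, path.subtrees[1:]):
            assert set(nxt.nodes) <= set(prev.nodes)

    def test_prune_at_alpha_matches_path(self, small_signal_cohort):
        tree = grow_tree(small_signal_cohort, GrowParams(min_split=10, min_leaf=5, cp=0.001))
        path = cost_complexity_path(tree)
        for alpha, sub in zip(path.alphas, path.subtrees):
            assert set(prune_at_alpha(tree, alpha * 1.0000001).nodes) == set(sub.nodes)


class TestSelectSubtreeCV:
    def test_pure_noise_selects_root_only_most_of_the_time(self, rng):
        hits = 0
        for rep in range(20):
            X = rng.normal(size=(300, 5))
            y = rng.integers(0, 2, 300)
            tree = select_subtree_cv(make_cohort(X, y), GrowParams(seed=rep))
            hits += tree.n_leaves == 1
        assert hits >= 18

    def test_strong_signal_keeps_both_planted_splits(self, rng):
        hits = 0
        for rep in range(10):
            X = rng.normal(size=(300, 5))
            y = ((X[:, 0] >= 0.0) & (X[:, 1] < 0.3)).astype(int)
            y = np.where(rng.random(300) < 0.05, 1 - y, y)
            tree = select_subtree_cv(make_cohort(X, y), GrowParams(seed=rep))
            covs = {tree.nodes[i].split.covariate for i in tree.internal_ids()}
            hits += {"x0", "x1"} <= covs
        assert hits >= 9

    def test_leave_one_out_matches_manual_computation(self):
        """v_folds = n on a 12-row fixture reproduces a by-hand LOO selection."""
        X = np.array([[1], [2], [3], [4], [5], [6], [7], [8], [9], [10], [11], [12]], dtype=float)
        y = np.array([0, 0, 0, 1, 0, 0, 1, 1, 0, 1, 1, 1])
        params = GrowParams(min_split=4, min_leaf=2, cp=0.0, v_folds=12, seed=3)
        cohort = make_cohort(X, y)
        selected, path = select_subtree_cv(cohort, params, return_path=True)

        # manual LOO: same fold ids, regrow on each 11-row subset, prune at
        # the geometric-mean alphas, score the held-out row
        rng = np.random.default_rng(params.seed)
        fold = stratified_fold_ids(y, 12, rng)
        K = len(path.alphas)
        betas = [
            np.sqrt(path.alphas[k] * path.alphas[k + 1]) if k < K - 1 else np.inf
            for k in range(K)
        ]
        errs = np.zeros(K)
        for i in range(12):
            keep = fold != fold[i]
            sub = make_cohort(X[keep], y[keep])
            t = grow_tree(sub, params)
            for k, beta in enumerate(betas):
                pred = prune_at_alpha(t, beta).predict_matrix(X[i : i + 1])[0]
                errs[k] += (y[i] - pred) ** 2
        errs /= 12
        np.testing.assert_allclose(path.cv_error, errs, atol=1e-12)
        best = errs.min()
        k_manual = max(k for k in range(K) if errs[k] <= best + 1e-12)
        assert selected.n_leaves == path.subtrees[k_manual].n_leaves

    def test_n_smaller_than_folds_is_an_error(self):
        X = np.arange(5, dtype=float).reshape(-1, 1)
        with pytest.raises(ValueError, match="v_folds"):
            select_subtree_cv(make_cohort(X, np.array([0, 1, 0, 1, 0])), GrowParams(min_split=4, min_leaf=2, v_folds=10))


class TestPredict:
    def test_root_only_tree_is_constant(self):
        X = np.arange(6, dtype=float).reshape(-1, 1)
        y = np.array([1, 0, 0, 1, 0, 0])
        tree = grow_tree(make_cohort(X, y), GrowParams(min_split=20, min_leaf=7))
        assert predict(tree, {"x0": 3.0}) == pytest.approx(1 / 3)
        assert predict(tree, {"x0": None}) == pytest.approx(1 / 3)

    def test_missing_root_covariate_follows_surrogate(self, small_signal_cohort):
        tree = grow_tree(small_signal_cohort, GrowParams(min_split=10, min_leaf=5))
        rule = tree.root.split
        child = tree.nodes[tree.root.children[0 if rule.surrogate_direction == "left" else 1]]
        row = {name: None for name in small_signal_cohort.names}
        expected = tree.predict_matrix(np.full((1, small_signal_cohort.p), np.nan))[0]
        assert predict(tree, row) == expected
        # the prediction comes from the surrogate-direction subtree
        sub_leaves = {tree.nodes[i].yhat for i in tree.leaf_ids(child.id)}
        assert expected in sub_leaves

    def test_mean_in_sample_prediction_is_prevalence(self, small_signal_cohort):
        tree = grow_tree(small_signal_cohort, GrowParams(min_split=10, min_leaf=5))
        preds = tree.predict_matrix(small_signal_cohort.X)
        assert preds.mean() == pytest.approx(small_signal_cohort.y.mean(), abs=1e-12)

    def test_unknown_covariate_is_an_error(self, small_signal_cohort):
        tree = grow_tree(small_signal_cohort, GrowParams(min_split=10, min_leaf=5))
        with pytest.raises(KeyError):
            predict(tree, {"nope": 1.0})


class TestSerialization:
    def test_json_round_trip_preserves_predictions(self, small_signal_cohort):
        tree = grow_tree(small_signal_cohort, GrowParams(min_split=10, min_leaf=5))
        back = RegressionTree.from_json(tree.to_json())
        np.testing.assert_array_equal(
            tree.predict_matrix(small_signal_cohort.X),
            back.predict_matrix(small_signal_cohort.X),
        )
        assert json.loads(tree.to_json()) == json.loads(back.to_json())
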