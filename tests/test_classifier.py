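import math

import numpy as np
import pytest

from fctmap.classifier import (
    BoostedTreeModel,
    TrainingPair,
    TreeNode,
    best_split,
    entropy,
    fit_boosted,
    fit_or_rule_boundary,
    grow_tree,
    predict_proba,
    prune,
)
from fctmap.classifier import _tree_proba
from helpers import brute_best_split


class TestEntropy:
    def test_maximal_two_class(self):
        assert entropy([5, 5]) == pytest.approx(1.0)

    def test_pure_set(self):
        assert entropy([10, 0]) == pytest.approx(0.0)

    def test_three_one(self):
        assert entropy([3, 1]) == pytest.approx(0.8113, abs=1e-4)

    def test_all_zero_is_an_error(self):
        with pytest.raises(ValueError):
            entropy([0, 0])


class TestBestSplit:
    def test_perfect_separation(self):
        x = np.array([1.0, 3, 5, 8, 12, 15, 20, 25])
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        cand = best_split(x, y)
        assert cand.threshold == pytest.approx(10.0)
        assert cand.gain == pytest.approx(entropy([4, 4]))

    def test_single_distinct_value_no_split(self):
        assert best_split(np.array([5.0, 5, 5, 5]), np.array([0, 1, 0, 1])) is None

    def test_missing_values_ignored(self):
        x = np.array([1.0, 2, np.nan, 10, 11, np.nan])
        y = np.array([1, 1, 0, 0, 0, 1])
        cand = best_split(x, y)
        assert cand.threshold == pytest.approx(6.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = np.round(rng.uniform(0, 100, size=8), 1)
        y = rng.integers(0, 2, size=8)
        if len(np.unique(y)) < 2:
            y[0] = 1 - y[0]
        mine = best_split(x, y)
        ref = brute_best_split(x, y)
        if ref is None:
            assert mine is None
        else:
            assert mine.threshold == pytest.approx(ref[0])
            assert mine.gain_ratio == pytest.approx(ref[1], abs=1e-9)
            assert mine.gain == pytest.approx(ref[2], abs=1e-9)


def _rule_data(n, seed, noise=0.0, theta1=75.0, theta2=5.0):
    rng = np.random.default_rng(seed)
    fuzzy = rng.uniform(0, 100, n)
    ediff = rng.uniform(0, 100, n)
    y = ((fuzzy > theta1) | (ediff < theta2)).astype(int)
    if noise:
        y = np.where(rng.random(n) < noise, 1 - y, y)
    return np.column_stack([fuzzy, ediff]), y


class TestGrowTree:
    def test_pure_input_single_leaf(self):
        X = np.array([[10.0, 5.0], [20.0, 8.0]])
        tree = grow_tree(X, np.array([1, 1]))
        assert tree.is_leaf

    def test_separable_rule_fits_exactly_with_few_nodes(self):
        X, y = _rule_data(200, seed=0)
        tree = grow_tree(X, y)
        pred = np.array([_tree_proba(tree, *row) >= 0.5 for row in X]).astype(int)
        assert (pred == y).all()
        internal = tree.n_nodes() - _count_leaves(tree)
        assert internal <= 3

    def test_depth_cap_gives_a_stump(self):
        X, y = _rule_data(100, seed=1)
        tree = grow_tree(X, y, max_depth=1)
        assert not tree.is_leaf
        assert tree.left.is_leaf and tree.right.is_leaf

    def test_chosen_splits_reduce_weighted_child_entropy(self):
        X, y = _rule_data(300, seed=2, noise=0.1)
        tree = grow_tree(X, y)

        def check(node):
            if node.is_leaf:
                return
            parent_h = entropy(node.counts)
            wl, wr = node.left.counts.sum(), node.right.counts.sum()
            child_h = (wl * entropy(node.left.counts) + wr * entropy(node.right.counts)) / (wl + wr)
            assert child_h <= parent_h + 1e-9
            check(node.left)
            check(node.right)

        check(tree)

    def test_matches_greedy_exhaustive_oracle_on_small_instance(self):
        # oracle: recursive exhaustive midpoint search, depth <= 3
        rng = np.random.default_rng(7)
        X = np.round(rng.uniform(0, 100, size=(30, 2)), 1)
        y = ((X[:, 0] > 60) & (X[:, 1] < 40)).astype(int)

        def oracle_predict(X_node, y_node, x, depth):
            if len(set(y_node)) == 1 or depth == 3 or len(y_node) < 4:
                return int(np.bincount(y_node, minlength=2).argmax())
            cands = []
            for f in (0, 1):
                ref = brute_best_split(X_node[:, f], y_node)
                if ref is not None and ref[1] > 1e-12:
                    cands.append((ref[1], -f, f, ref[0]))
            if not cands:
                return int(np.bincount(y_node, minlength=2).argmax())
            _, _, f, thr = max(cands)
            mask = X_node[:, f] <= thr
            if x[f] <= thr:
                return oracle_predict(X_node[mask], y_node[mask], x, depth + 1)
            return oracle_predict(X_node[~mask], y_node[~mask], x, depth + 1)

        tree = grow_tree(X, y, max_depth=3)
        for i in range(len(y)):
            mine = int(_tree_proba(tree, X[i, 0], X[i, 1]) >= 0.5)
            assert mine == oracle_predict(X, y, X[i], 0)


def _count_leaves(node):
    if node.is_leaf:
        return 1
    return _count_leaves(node.left) + _count_leaves(node.right)


class TestPrune:
    def test_no_pessimism_keeps_separable_tree(self):
        X, y = _rule_data(200, seed=3)
        tree = grow_tree(X, y)
        n_before = tree.n_nodes()
        assert prune(tree, confidence=1.0).n_nodes() == n_before

    def test_same_class_children_collapse(self):
        leaf_a = TreeNode(counts=np.array([1.0, 3.0]))
        leaf_b = TreeNode(counts=np.array([0.0, 4.0]))
        parent = TreeNode(counts=np.array([1.0, 7.0]), feature=0, threshold=50.0,
                          left=leaf_a, right=leaf_b)
        assert prune(parent, confidence=0.25).is_leaf

    def test_pruned_tree_never_larger(self):
        X, y = _rule_data(400, seed=4, noise=0.15)
        tree = grow_tree(X, y)
        n_before = tree.n_nodes()
        pruned = prune(tree, confidence=0.25)
        assert pruned.n_nodes() <= n_before


class TestFitBoosted:
    def test_single_trial_equals_single_pruned_tree(self):
        X, y = _rule_data(300, seed=5, noise=0.05)
        pairs = [(X[i, 0], X[i, 1], int(y[i])) for i in range(len(y))]
        model = fit_boosted(pairs, n_trials=1)
        single = prune(grow_tree(X, y), confidence=0.25)
        for i in range(0, len(y), 7):
            assert predict_proba(model, X[i, 0], X[i, 1]) == pytest.approx(
                _tree_proba(single, X[i, 0], X[i, 1])
            )

    def test_boosted_stumps_beat_one_stump_on_or_data(self):
        X, y = _rule_data(400, seed=6, theta1=60.0, theta2=30.0)
        pairs = [(X[i, 0], X[i, 1], int(y[i])) for i in range(len(y))]
        one = fit_boosted(pairs, n_trials=1, max_depth=1)
        many = fit_boosted(pairs, n_trials=10, max_depth=1)
        acc_one = np.mean((one.predict_proba_many(X[:, 0], X[:, 1]) >= 0.5) == y)
        acc_many = np.mean((many.predict_proba_many(X[:, 0], X[:, 1]) >= 0.5) == y)
        assert acc_many > acc_one

    def test_separable_data_reaches_zero_training_error(self):
        X, y = _rule_data(300, seed=7)
        pairs = [(X[i, 0], X[i, 1], int(y[i])) for i in range(len(y))]
        model = fit_boosted(pairs, n_trials=10)
        pred = (model.predict_proba_many(X[:, 0], X[:, 1]) >= 0.5).astype(int)
        assert (pred == y).all()

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            fit_boosted([(90.0, 1.0, 1), (80.0, 2.0, 1)], n_trials=3)

    def test_deterministic_serialization(self):
        X, y = _rule_data(200, seed=8, noise=0.05)
        pairs = [TrainingPair(X[i, 0], X[i, 1], "plausible" if y[i] else "non_plausible")
                 for i in range(len(y))]
        m1 = fit_boosted(pairs, n_trials=5)
        m2 = fit_boosted(pairs, n_trials=5)
        assert m1.to_json() == m2.to_json()

    def test_json_roundtrip_preserves_predictions(self):
        X, y = _rule_data(150, seed=9, noise=0.05)
        pairs = [(X[i, 0], X[i, 1], int(y[i])) for i in range(len(y))]
        model = fit_boosted(pairs, n_trials=5)
        clone = BoostedTreeModel.from_json(model.to_json())
        for f, e in [(10, 50), (80, 3), (95, None), (50, 20)]:
            assert clone.predict_proba(f, e) == pytest.approx(model.predict_proba(f, e))


class TestPredictProba:
    def test_high_fuzzy_region_is_confident(self):
        rng = np.random.default_rng(10)
        fuzzy = rng.uniform(0, 100, 500)
        ediff = rng.uniform(0, 100, 500)
        y = (fuzzy >= 90).astype(int)
        model = fit_boosted([(fuzzy[i], ediff[i], int(y[i])) for i in range(500)], n_trials=5)
        assert model.predict_proba(95.0, 0.0) > 0.9

    def test_laplace_on_single_leaf(self):
        leaf = TreeNode(counts=np.array([0.0, 7.0]))
        model = BoostedTreeModel(trees=[leaf], stage_weights=[1.0])
        assert predict_proba(model, 50, 10) == pytest.approx((7 + 1) / (7 + 2))

    def test_probabilities_complement(self):
        leaf = TreeNode(counts=np.array([3.0, 5.0]))
        p1 = leaf.leaf_probability()
        p0 = (leaf.counts[0] + 1) / (leaf.counts.sum() + 2)
        assert p0 + p1 == pytest.approx(1.0)

    def test_missing_ediff_routes_fractionally(self):
        X, y = _rule_data(300, seed=11, theta1=200.0, theta2=50.0)  # ediff-only rule
        model = fit_boosted([(X[i, 0], X[i, 1], int(y[i])) for i in range(300)], n_trials=1)
        p_missing = model.predict_proba(50.0, None)
        p_low = model.predict_proba(50.0, 5.0)
        p_high = model.predict_proba(50.0, 95.0)
        assert min(p_low, p_high) - 1e-9 <= p_missing <= max(p_low, p_high) + 1e-9

    def test_output_in_unit_interval(self):
        X, y = _rule_data(200, seed=12, noise=0.1)
        model = fit_boosted([(X[i, 0], X[i, 1], int(y[i])) for i in range(200)], n_trials=5)
        for f in (0, 25, 50, 75, 100):
            for e in (None, 0, 50, 100):
                assert 0.0 <= model.predict_proba(f, e) <= 1.0


class TestParameterRecovery:
    def test_recovers_rule_thresholds_one_seed(self):
        # the full 5-seed sweep lives in the acceptance suite
        rng = np.random.default_rng(0)
        n = 2000
        fuzzy = rng.uniform(0, 100, n)
        ediff = rng.uniform(0, 100, n)
        y = ((fuzzy > 75) | (ediff < 25)).astype(int)
        y = np.where(rng.random(n) < 0.05, 1 - y, y)
        model = fit_boosted([(fuzzy[i], ediff[i], int(y[i])) for i in range(n)], n_trials=10)
        t1, t2 = fit_or_rule_boundary(model)
        assert abs(t1 - 75) <= 3
        assert abs(t2 - 25) <= 3
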