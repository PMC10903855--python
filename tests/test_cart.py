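import json

import numpy as np
import pandas as pd
import pytest

from dgcart.cart import (
    TreeSpec,
    best_split,
    classify_units,
    delta_variation,
    gini_impurity,
    grow_classification_tree,
    grow_regression_tree,
    predict_values,
    variance_impurity,
)

from oracles import brute_force_best_split


class TestImpurities:
    @pytest.mark.parametrize(
        "counts,expected",
        [((5, 5), 0.5), ((7, 0), 0.0), ((3, 1), 0.375), ((1, 1, 1, 1), 0.75)],
    )
    def test_gini_examples(self, counts, expected):
        assert gini_impurity(counts) == pytest.approx(expected)

    def test_gini_rejects_degenerate_counts(self):
        with pytest.raises(ValueError):
            gini_impurity((0, 0))
        with pytest.raises(ValueError):
            gini_impurity((-1, 3))

    @pytest.mark.parametrize(
        "values,expected",
        [((3.0, 3.0, 3.0), 0.0), ((4.2,), 0.0), ((1.0, 3.0), 1.0)],
    )
    def test_variance_examples(self, values, expected):
        assert variance_impurity(values) == pytest.approx(expected)

    def test_variance_rejects_empty(self):
        with pytest.raises(ValueError):
            variance_impurity([])


class TestDeltaVariation:
    def test_identical_partitions_give_zero(self):
        values = np.array([0, 1, 1, 0, 1])
        part = [np.arange(5)]
        assert delta_variation(part, part, values) == 0.0

    def test_pure_split_of_balanced_membership_reduces_by_quarter(self):
        # lambda-hat = 0.5 at the parent, two pure children: the pooled
        # variance drops from lambda(1-lambda) = 0.25 to 0
        a = np.array([1, 1, 0, 0])
        red = delta_variation([np.arange(4)], [np.array([0, 1]), np.array([2, 3])], a)
        assert red == pytest.approx(0.25)

    def test_refinement_never_increases_pooled_variance(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            values = rng.normal(size=12)
            mid = rng.integers(1, 11)
            parent = [np.arange(mid), np.arange(mid, 12)]
            cut = rng.integers(1, mid) if mid > 1 else 1
            child = [np.arange(cut), np.arange(cut, mid), np.arange(mid, 12)]
            assert delta_variation(parent, child, values) >= -1e-12

    def test_non_nested_partitions_rejected(self):
        values = np.arange(4.0)
        parent = [np.array([0, 1]), np.array([2, 3])]
        child = [np.array([0, 2]), np.array([1, 3])]
        with pytest.raises(ValueError):
            delta_variation(parent, child, values)


class TestBestSplit:
    def test_perfect_separation_found_with_pure_children(self):
        X = np.array([[0.0], [0.1], [0.2], [1.0], [1.1], [1.2]])
        labels = [1, 1, 1, 2, 2, 2]
        sp = best_split(X, labels, "gini", TreeSpec())
        assert sp.feature == 0
        assert 0.2 < sp.threshold < 1.0
        assert sp.gain == pytest.approx(0.5)  # parent gini 0.5, children pure

    def test_constant_covariates_yield_no_split(self):
        X = np.ones((6, 2))
        assert best_split(X, [1, 2, 1, 2, 1, 2], "gini", TreeSpec()) is None

    def test_min_split_gate(self):
        X = np.arange(3.0).reshape(-1, 1)
        assert best_split(X, [1, 2, 2], "gini", TreeSpec(min_split=5)) is None

    def test_min_bucket_restricts_candidate_cuts(self):
        X = np.arange(6.0).reshape(-1, 1)
        y = [0.0, 0.0, 0.0, 0.0, 0.0, 10.0]
        sp = best_split(X, y, "variance", TreeSpec(min_split=4, min_bucket=2))
        # isolating the single outlier is inadmissible; cut must leave >= 2
        assert sp is None or min(sp.left_mask.sum(), (~sp.left_mask).sum()) >= 2

    def test_cp_gate_blocks_weak_splits(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 1))
        y = rng.normal(size=20)  # pure noise: relative improvement is small
        assert best_split(X, y, "variance", TreeSpec(cp=0.9)) is None

    def test_unknown_criterion_rejected(self):
        with pytest.raises(ValueError):
            best_split(np.zeros((3, 1)), [1, 2, 1], "entropy", TreeSpec())


class TestGrowClassification:
    def test_single_class_gives_single_leaf(self):
        X = np.arange(6.0).reshape(-1, 1)
        t = grow_classification_tree(X, [1] * 6)
        assert t.n_leaves == 1 and t.nodes[0].label == 1

    def test_delta_o_above_any_reduction_gives_single_leaf(self):
        X = np.array([[0.0], [0.1], [1.0], [1.1]])
        labels = [1, 1, 2, 2]
        # a perfect balanced split reduces pooled membership variance by 0.25
        t = grow_classification_tree(X, labels, TreeSpec(delta_o=0.3))
        assert t.n_leaves == 1
        t2 = grow_classification_tree(X, labels, TreeSpec(delta_o=0.2))
        assert t2.n_leaves == 2

    def test_linearly_separable_data_gives_depth_one_pure_leaves(self):
        X = np.array([[0.0], [0.2], [0.4], [5.0], [5.2], [5.4]])
        t = grow_classification_tree(X, [1, 1, 1, 2, 2, 2])
        assert t.depth == 1 and t.n_leaves == 2
        leaves = [nd for nd in t.nodes if nd.is_leaf]
        assert sorted(nd.label for nd in leaves) == [1, 2]
        assert all(nd.impurity == 0 for nd in leaves)

    def test_majority_guard_rejects_split_leaving_singleton_majority(self):
        # the only improving cut isolates one unit of stratum 2, whose leaf
        # majority would rest on a single observation
        X = np.array([[0.0], [1.0], [2.0]])
        t = grow_classification_tree(X, [1, 1, 2], TreeSpec(min_split=2))
        assert t.n_leaves == 1

    def test_fewer_than_two_rows_rejected(self):
        with pytest.raises(ValueError):
            grow_classification_tree(np.zeros((1, 1)), [1])


class TestGrowRegression:
    def test_constant_outcome_gives_single_leaf_with_that_mean(self):
        X = np.arange(5.0).reshape(-1, 1)
        t = grow_regression_tree(X, [7.5] * 5)
        assert t.n_leaves == 1 and t.nodes[0].mean == pytest.approx(7.5)

    def test_step_function_recovered_at_depth_one(self):
        X = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        y = [3.0, 3.0, 3.0, 8.0, 8.0, 8.0]
        t = grow_regression_tree(X, y)
        assert t.depth == 1
        means = sorted(nd.mean for nd in t.nodes if nd.is_leaf)
        assert means == pytest.approx([3.0, 8.0])

    def test_max_depth_caps_leaf_count(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 3))
        y = rng.normal(size=40)
        t = grow_regression_tree(X, y, TreeSpec(max_depth=1))
        assert t.n_leaves <= 2
        assert t.depth <= 1


class TestPrediction:
    def test_majority_vote_labels_and_deterministic_tie_break(self):
        # one leaf holds counts (3, 7): every routed unit gets stratum 2
        X = np.array([[0.0]] * 3 + [[1.0]] * 7)
        labels = [1, 1, 1, 2, 2, 2, 2, 2, 2, 2]
        t = grow_classification_tree(X, labels, TreeSpec(max_depth=0))
        assert t.nodes[0].class_counts.tolist() == [3, 7]
        assert np.all(classify_units(t, np.array([[5.0], [-1.0]])) == 2)
        # balanced counts (5, 5): tie broken toward the lowest stratum
        t2 = grow_classification_tree(
            np.zeros((10, 1)), [1] * 5 + [2] * 5, TreeSpec(max_depth=0)
        )
        assert np.all(classify_units(t2, np.zeros((4, 1))) == 1)

    def test_leaf_mean_prediction(self):
        X = np.zeros((3, 1))
        t = grow_regression_tree(X, [2.0, 4.0, 6.0])
        assert np.all(predict_values(t, np.zeros((5, 1))) == pytest.approx(4.0))

    def test_predictions_take_at_most_leaf_count_distinct_values(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 4))
        y = rng.normal(size=60)
        t = grow_regression_tree(X, y, TreeSpec(min_split=10))
        preds = predict_values(t, rng.normal(size=(500, 4)))
        assert len(np.unique(preds)) <= t.n_leaves

    def test_kind_mismatch_rejected(self):
        X = np.zeros((4, 1))
        reg = grow_regression_tree(X, [1.0, 2.0, 3.0, 4.0])
        cls = grow_classification_tree(X, [1, 1, 2, 2])
        with pytest.raises(ValueError):
            classify_units(reg, X)
        with pytest.raises(ValueError):
            predict_values(cls, X)


class TestCategoricalCovariates:
    def test_predictive_categorical_column_is_split_on(self):
        X = pd.DataFrame({"g": ["a", "a", "b", "b", "c", "c"]})
        y = [1.0, 1.2, 5.0, 5.2, 1.1, 0.9]
        t = grow_regression_tree(X, y)
        root = t.nodes[0]
        assert root.left_categories is not None
        # category b (high mean) separated from a and c
        assert {"b"} in (set(root.left_categories), set(root.right_categories))

    def test_unseen_level_routes_to_larger_child(self):
        X = pd.DataFrame({"g": ["a"] * 4 + ["b"] * 2})
        y = [1.0, 1.1, 0.9, 1.0, 9.0, 9.2]
        t = grow_regression_tree(X, y)
        pred = predict_values(t, pd.DataFrame({"g": ["zz"]}))
        # larger child holds the four 'a' rows with mean ~1
        assert pred[0] == pytest.approx(1.0)


class TestTreeInvariants:
    @pytest.mark.parametrize("criterion", ["gini", "variance"])
    def test_pooled_child_impurity_never_exceeds_parent(self, criterion):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(80, 3))
        target = (
            rng.integers(1, 3, size=80) if criterion == "gini" else rng.normal(size=80)
        )
        grow = grow_classification_tree if criterion == "gini" else grow_regression_tree
        t = grow(X, target, TreeSpec(min_split=5))
        for nd in t.nodes:
            if not nd.is_leaf:
                l, r = t.nodes[nd.left], t.nodes[nd.right]
                pooled = (l.n * l.impurity + r.n * r.impurity) / nd.n
                assert pooled <= nd.impurity + 1e-12

    def test_refitting_is_idempotent(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(50, 3))
        y = rng.normal(size=50)
        a = grow_regression_tree(X, y, TreeSpec(min_split=5)).to_dict()
        b = grow_regression_tree(X, y, TreeSpec(min_split=5)).to_dict()
        assert a == b

    def test_every_row_lands_in_exactly_one_leaf(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(60, 3))
        labels = rng.integers(1, 4, size=60)
        t = grow_classification_tree(X, labels, TreeSpec(min_split=5))
        leaf_ids = {nd.id for nd in t.nodes if nd.is_leaf}
        applied = t.apply(X)
        assert set(applied) <= leaf_ids
        # training rows partition across leaves: leaf counts sum to n_train
        assert sum(nd.n for nd in t.nodes if nd.is_leaf) == 60
        counts = {nd.id: nd.n for nd in t.nodes if nd.is_leaf}
        for leaf in leaf_ids:
            assert int(np.sum(applied == leaf)) == counts[leaf]

    def test_json_export_is_serialisable_and_complete(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(30, 2))
        t = grow_classification_tree(X, rng.integers(1, 3, size=30), TreeSpec(min_split=5))
        payload = json.loads(t.to_json())
        assert payload["kind"] == "classification"
        assert len(payload["nodes"]) == len(t.nodes)
        leaves = [nd for nd in payload["nodes"] if "left" not in nd]
        assert all("class_counts" in nd and "label" in nd for nd in leaves)


class TestSplitSearchOracle:
    @pytest.mark.parametrize("criterion", ["gini", "variance"])
    def test_matches_brute_force_on_small_random_datasets(self, criterion):
        """Spot check against exhaustive enumeration (the full 100-case
        sweep runs in the acceptance suite)."""
        rng = np.random.default_rng(100)
        for _ in range(20):
            n = int(rng.integers(5, 31))
            p = int(rng.integers(1, 4))
            X = np.round(rng.normal(size=(n, p)), 2)  # rounded: forces ties
            target = (
                rng.integers(1, 3, size=n)
                if criterion == "gini"
                else rng.normal(size=n)
            )
            mine = best_split(X, target, criterion, TreeSpec())
            oracle = brute_force_best_split(X, target, criterion)
            if oracle is None:
                assert mine is None
            else:
                gain, j, thr, unique = oracle
                assert mine is not None
                assert mine.gain == pytest.approx(gain, abs=1e-9)
                if unique:
                    assert (mine.feature, mine.threshold) == (j, pytest.approx(thr))
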