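"""Forest correctness: split search vs exhaustive oracle, importance, metrics."""

import numpy as np
import pandas as pd
import pytest

from famtrait.forest import (
    LEAF,
    ForestParams,
    fit_forest,
    gini_impurity,
    gini_importance,
    grid_search,
    grow_tree,
    predict_proba,
    select_top_features,
)
from famtrait.metrics import (
    auc_pr,
    auc_roc,
    confusion_matrix,
    f1_score,
    pr_curve,
    roc_curve,
)

# ---------------------------------------------------------------------------
# independent oracle: pure-python exhaustive CART with the same contracts
# (left = values <= midpoint threshold; ties -> lowest feature, lowest
# threshold; stop on purity, depth, or no impurity decrease)
# ---------------------------------------------------------------------------


def oracle_gini(labels):
    n = len(labels)
    p1 = sum(labels) / n
    return 1.0 - p1 * p1 - (1 - p1) * (1 - p1)


def oracle_best_split(X, y):
    n, F = X.shape
    parent = oracle_gini(y)
    best = None
    for f in range(F):
        values = sorted(set(X[:, f]))
        for a, b in zip(values, values[1:]):
            thr = (a + b) / 2
            left = [y[i] for i in range(n) if X[i, f] <= thr]
            right = [y[i] for i in range(n) if X[i, f] > thr]
            gain = parent - (
                len(left) * oracle_gini(left) + len(right) * oracle_gini(right)
            ) / n
            if gain > 1e-12 and (best is None or gain > best[0] + 1e-12):
                best = (gain, f, thr)
    return best


def oracle_tree(X, y, depth=0, max_depth=None):
    """Nested-dict CART grown by exhaustive search."""
    counts = (int(np.sum(y == 0)), int(np.sum(y == 1)))
    node = {"counts": counts}
    if 0 in counts or (max_depth is not None and depth >= max_depth):
        return node
    split = oracle_best_split(X, y)
    if split is None:
        return node
    _, f, thr = split
    mask = X[:, f] <= thr
    node.update(
        feature=f, threshold=thr,
        left=oracle_tree(X[mask], y[mask], depth + 1, max_depth),
        right=oracle_tree(X[~mask], y[~mask], depth + 1, max_depth),
    )
    return node


def assert_same_tree(tree, node, oracle_node):
    counts = tuple(int(c) for c in tree.value[node])
    assert counts == oracle_node["counts"]
    if "feature" in oracle_node:
        assert tree.feature[node] == oracle_node["feature"]
        assert tree.threshold[node] == pytest.approx(oracle_node["threshold"])
        assert_same_tree(tree, tree.left[node], oracle_node["left"])
        assert_same_tree(tree, tree.right[node], oracle_node["right"])
    else:
        assert tree.feature[node] == LEAF


def random_instance(seed, max_n=10, max_f=4):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, max_n + 1))
    F = int(rng.integers(1, max_f + 1))
    X = rng.integers(0, 4, (n, F)).astype(float)
    y = rng.integers(0, 2, n)
    return X, y


class TestGiniImpurity:
    @pytest.mark.parametrize(
        "counts,expected",
        [((3, 3), 0.5), ((5, 0), 0.0), ((2, 6), 0.375)],
    )
    def test_known_values(self, counts, expected):
        assert gini_impurity(counts) == pytest.approx(expected)

    def test_empty_node_rejected(self):
        with pytest.raises(ValueError):
            gini_impurity((0, 0))


class TestGrowTree:
    def test_single_clean_split(self):
        X = np.array([[0.0], [0.0], [5.0], [5.0]])
        y = np.array([0, 0, 1, 1])
        tree = grow_tree(X, y)
        assert tree.feature[0] == 0
        assert tree.threshold[0] == pytest.approx(2.5)
        assert tree.feature[tree.left[0]] == LEAF
        assert tree.feature[tree.right[0]] == LEAF

    def test_pure_labels_give_single_leaf(self):
        tree = grow_tree(np.zeros((4, 2)), np.ones(4, dtype=int))
        assert tree.n_nodes == 1 and tree.feature[0] == LEAF

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_exhaustive_oracle(self, seed):
        X, y = random_instance(seed)
        tree = grow_tree(X, y)
        assert_same_tree(tree, 0, oracle_tree(X, y))

    def test_max_depth_is_respected(self):
        X, y = random_instance(123, max_n=10)
        tree = grow_tree(X, y, max_depth=1)
        assert tree.depth() <= 1
        assert_same_tree(tree, 0, oracle_tree(X, y, max_depth=1))


class TestForest:
    def test_same_seed_same_predictions(self):
        X, y = random_instance(7, max_n=10, max_f=4)
        p1 = predict_proba(fit_forest(X, y, ForestParams(10, 5), seed=3), X)
        p2 = predict_proba(fit_forest(X, y, ForestParams(10, 5), seed=3), X)
        np.testing.assert_array_equal(p1, p2)

    def test_single_tree_no_bagging_reduces_to_grow_tree(self):
        X, y = random_instance(11)
        params = ForestParams(n_estimators=1, max_depth=None,
                              max_features=None, bootstrap=False)
        model = fit_forest(X, y, params, seed=0)
        assert_same_tree(model.trees[0], 0, oracle_tree(X, y))

    def test_separable_data_fits_perfectly(self):
        X = np.arange(10, dtype=float).reshape(-1, 1)
        y = (X[:, 0] >= 5).astype(int)
        model = fit_forest(X, y, ForestParams(25, None), seed=0)
        preds = (predict_proba(model, X) >= 0.5).astype(int)
        np.testing.assert_array_equal(preds, y)

    def test_label_flip_complements_probabilities(self):
        X, y = random_instance(19, max_n=10)
        p = predict_proba(fit_forest(X, y, ForestParams(20, 4), seed=5), X)
        q = predict_proba(fit_forest(X, 1 - y, ForestParams(20, 4), seed=5), X)
        np.testing.assert_allclose(p, 1 - q, atol=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_forest(np.zeros((4, 2)), np.zeros(4, dtype=int),
                       ForestParams(2, 2), seed=0)


class TestGiniImportance:
    def params(self, n=1):
        return ForestParams(n_estimators=n, max_depth=None,
                            max_features=None, bootstrap=False)

    def test_single_split_gets_all_importance(self):
        X = np.array([[0, 7], [0, 7], [5, 7], [5, 7]], dtype=float)
        y = np.array([0, 0, 1, 1])
        imp = gini_importance(fit_forest(X, y, self.params(), seed=0))
        lookup = imp.set_index("family")["importance"]
        assert lookup[0] == pytest.approx(1.0)
        assert lookup[1] == 0.0

    def test_stump_fixture_matches_hand_computed_weights(self):
        # root: 8 samples, 3 zeros / 5 ones; splits on f0 -> left (4 samples,
        # 3/1), right pure 1s.  left then splits on f1 into pure leaves.
        X = np.array([
            [0, 0], [0, 0], [0, 0], [0, 1],
            [1, 0], [1, 0], [1, 0], [1, 0],
        ], dtype=float)
        y = np.array([0, 0, 0, 1, 1, 1, 1, 1])
        model = fit_forest(X, y, self.params(), seed=0)
        imp = gini_importance(model).set_index("family")["importance"]
        root_gini = 1 - (3 / 8) ** 2 - (5 / 8) ** 2
        left_gini = 1 - (3 / 4) ** 2 - (1 / 4) ** 2
        d_root = root_gini - (4 / 8) * left_gini - (4 / 8) * 0.0
        d_left = (4 / 8) * (left_gini - 0.0)
        total = d_root + d_left
        assert imp[0] == pytest.approx(d_root / total)
        assert imp[1] == pytest.approx(d_left / total)

    def test_importances_sum_to_one_and_unused_are_zero(self):
        X, y = random_instance(31, max_n=10, max_f=4)
        model = fit_forest(X, y, ForestParams(30, 5), seed=2)
        imp = gini_importance(model)
        assert imp["importance"].sum() == pytest.approx(1.0)
        used = {f for t in model.trees for f in t.feature[t.feature != LEAF]}
        unused = set(range(X.shape[1])) - used
        lookup = imp.set_index("family")["importance"]
        assert all(lookup[f] == 0.0 for f in unused)
        assert sorted(imp["rank"]) == list(range(1, X.shape[1] + 1))


class TestSelectTopFeatures:
    def test_all_features_returned_ranked(self):
        X, y = random_instance(41, max_n=10, max_f=4)
        sel = select_top_features(X, y, n_select=X.shape[1],
                                  params=ForestParams(10, 4), seed=1)
        assert sorted(sel) == list(range(X.shape[1]))

    def test_deterministic_per_seed(self):
        X, y = random_instance(43, max_n=10, max_f=4)
        a = select_top_features(X, y, 2, ForestParams(10, 4), seed=9)
        b = select_top_features(X, y, 2, ForestParams(10, 4), seed=9)
        assert a == b


class TestGridSearch:
    def folds(self, n, k=3):
        idx = np.arange(n)
        return [idx[i::k] for i in range(k)]

    def test_single_cell_grid_returns_it(self):
        X, y = random_instance(51, max_n=10)
        best, table = grid_search(
            X, y, self.folds(len(y)),
            {"n_estimators": [7], "max_depth": [3]},
        )
        assert best.n_estimators == 7 and best.max_depth == 3
        assert len(table) == 1

    def test_table_covers_the_grid(self):
        rng = np.random.default_rng(53)
        X = rng.integers(0, 4, (12, 3)).astype(float)
        y = np.array([0, 1] * 6)  # balanced so every fold's complement has both classes
        grid = {"n_estimators": [5, 10], "max_depth": [2, 4],
                "max_features": ["sqrt"]}
        _, table = grid_search(X, y, self.folds(len(y)), grid)
        assert len(table) == 4

    def test_separable_data_prefers_smallest_perfect_model(self):
        X = np.repeat(np.arange(12, dtype=float), 1).reshape(-1, 1)
        y = (X[:, 0] >= 6).astype(int)
        best, table = grid_search(
            X, y, self.folds(12), {"n_estimators": [5, 20], "max_depth": [3]},
        )
        top = table["mean_cv_f1"].max()
        assert table.loc[
            table["n_estimators"] == best.n_estimators, "mean_cv_f1"
        ].iloc[0] == pytest.approx(top)


class TestMetrics:
    def test_hand_counted_roc_auc(self):
        scores = [0.9, 0.8, 0.3, 0.1]
        labels = [1, 0, 1, 0]
        assert auc_roc(scores, labels) == pytest.approx(0.75)

    def test_perfect_ranking(self):
        assert auc_roc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_constant_scores_give_half(self):
        assert auc_roc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == pytest.approx(0.5)

    def test_hand_counted_pr_auc(self):
        # sweep: R/P pairs (0.5, 1), (0.5, 0.5), (1, 2/3), (1, 0.5)
        value = auc_pr([0.9, 0.8, 0.3, 0.1], [1, 0, 1, 0])
        expected = 0.5 * 1.0 + 0.5 * (0.5 + 2 / 3) / 2
        assert value == pytest.approx(expected)

    def test_one_class_labels_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([0.1, 0.2], [1, 1])

    def test_roc_auc_matches_sklearn_on_random_data(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(50):
            n = int(rng.integers(6, 40))
            labels = rng.integers(0, 2, n)
            if len(np.unique(labels)) < 2:
                continue
            scores = np.round(rng.random(n), 2)  # force ties sometimes
            assert auc_roc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )

    def test_f1_is_harmonic_mean(self):
        labels = [1, 1, 0, 0, 1]
        preds = [1, 0, 1, 0, 1]
        p, r = 2 / 3, 2 / 3
        assert f1_score(labels, preds) == pytest.approx(2 * p * r / (p + r))

    def test_confusion_rows_normalize(self):
        cm = confusion_matrix([0, 0, 1, 1, 1], [0, 1, 1, 1, 0], normalize=True)
        np.testing.assert_allclose(cm.sum(axis=1), [1.0, 1.0])
        assert cm[0, 0] == pytest.approx(0.5)
        assert cm[1, 1] == pytest.approx(2 / 3)


class TestAgreementWithEstablishedForest:
    """Sanity harness: our forest should broadly agree with an established
    random-forest implementation on the same data (correlated predictions,
    overlapping top importances) — not match it exactly."""

    def test_predictions_correlate_with_sklearn(self, small_dataset):
        from sklearn.ensemble import RandomForestClassifier

        inst = small_dataset.instances
        X = inst.drop(columns="class")
        y = inst["class"].to_numpy()
        ours = fit_forest(X, y, ForestParams(100, 10), seed=0)
        p_ours = predict_proba(ours, X)
        skl = RandomForestClassifier(
            n_estimators=100, max_depth=10, random_state=0
        ).fit(X.to_numpy(), y)
        p_skl = skl.predict_proba(X.to_numpy())[:, 1]
        assert np.corrcoef(p_ours, p_skl)[0, 1] > 0.8
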