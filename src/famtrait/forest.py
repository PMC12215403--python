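"""A native random-forest classifier for gene-family count features.

Bagged CART trees with Gini split criterion, per-node feature subsampling,
mean-decrease-in-impurity (Gini) importance, feature selection, and a full
grid search.  The implementation is deliberately single-threaded and
deterministic: given the same data and seed, a fitted forest and all its
predictions are bit-identical across runs.

Trees use a flat array representation (parallel arrays indexed by node id),
which keeps growth, prediction, importance, and Shapley traversal simple and
fast.  The split convention is: samples with ``x[feature] <= threshold`` go
left; thresholds are midpoints of consecutive distinct sorted values.
Tie-breaks in the split search are deterministic (lowest feature index, then
lowest threshold).
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Tree",
    "ForestParams",
    "ForestModel",
    "gini_impurity",
    "grow_tree",
    "fit_forest",
    "predict_proba",
    "gini_importance",
    "select_top_features",
    "grid_search",
]

LEAF = -1


def gini_impurity(class_counts) -> float:
    """Gini impurity 1 - sum(p_k^2) of a node's class-count vector."""
    counts = np.asarray(class_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("class counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise ValueError("cannot compute impurity of an empty node")
    p = counts / total
    return float(1.0 - np.sum(p * p))


@dataclass
class Tree:
    """Flat-array CART tree.  Node 0 is the root; ``feature == LEAF`` marks leaves.

    ``value[i]`` holds the per-class sample counts that reached node ``i``
    during growth (bootstrap counts), so a leaf's class-1 probability is
    ``value[i, 1] / value[i].sum()``.
    """

    feature: np.ndarray  # int, LEAF for leaves
    threshold: np.ndarray  # float, NaN for leaves
    left: np.ndarray  # int child ids, -1 for leaves
    right: np.ndarray
    value: np.ndarray  # (n_nodes, n_classes) float sample counts
    impurity: np.ndarray  # float per node

    @property
    def n_nodes(self) -> int:
        return len(self.feature)

    def leaf_probability(self, node: int) -> float:
        v = self.value[node]
        return float(v[1] / v.sum())

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Vectorized class-1 probability for a (n, n_features) array."""
        node = np.zeros(len(X), dtype=np.intp)
        active = self.feature[node] != LEAF
        while active.any():
            idx = np.flatnonzero(active)
            cur = node[idx]
            go_left = X[idx, self.feature[cur]] <= self.threshold[cur]
            node[idx] = np.where(go_left, self.left[cur], self.right[cur])
            active[idx] = self.feature[node[idx]] != LEAF
        return self.value[node, 1] / self.value[node].sum(axis=1)

    def depth(self) -> int:
        depths = np.zeros(self.n_nodes, dtype=int)
        for i in range(self.n_nodes):
            if self.feature[i] != LEAF:
                depths[self.left[i]] = depths[i] + 1
                depths[self.right[i]] = depths[i] + 1
        return int(depths.max())

    def to_dict(self) -> dict:
        return {
            "feature": self.feature.tolist(),
            "threshold": [None if np.isnan(t) else t for t in self.threshold],
            "left": self.left.tolist(),
            "right": self.right.tolist(),
            "value": self.value.tolist(),
            "impurity": self.impurity.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Tree":
        thr = np.array(
            [np.nan if t is None else t for t in d["threshold"]], dtype=float
        )
        return cls(
            feature=np.asarray(d["feature"], dtype=np.intp),
            threshold=thr,
            left=np.asarray(d["left"], dtype=np.intp),
            right=np.asarray(d["right"], dtype=np.intp),
            value=np.asarray(d["value"], dtype=float),
            impurity=np.asarray(d["impurity"], dtype=float),
        )


def _n_candidate_features(rule, n_features: int) -> int:
    if rule is None or rule == "all":
        return n_features
    if rule == "sqrt":
        return max(1, int(math.sqrt(n_features)))
    if rule == "log2":
        return max(1, int(math.log2(n_features))) if n_features > 1 else 1
    if isinstance(rule, (int, np.integer)) and not isinstance(rule, bool):
        return min(n_features, max(1, int(rule)))
    if isinstance(rule, float):
        if not 0 < rule <= 1:
            raise ValueError("fractional max_features must be in (0, 1]")
        return max(1, int(rule * n_features))
    raise ValueError(f"unknown max_features rule {rule!r}")


def _best_split(X, y, idx, feature_ids, parent_impurity):
    """Best (feature, threshold, gain) over the candidate features at a node.

    Returns ``None`` when no split yields a positive impurity decrease.
    Candidate thresholds are midpoints of consecutive distinct sorted values.
    Deterministic tie-break: features are scanned in ascending index order and
    thresholds ascend within a feature, and only a strictly larger gain
    replaces the incumbent.
    """
    n = len(idx)
    y_node = y[idx]
    best = None  # (gain, feature, threshold)
    for f in np.sort(feature_ids):
        v = X[idx, f]
        order = np.argsort(v, kind="stable")
        vs = v[order]
        ys = y_node[order]
        cut = np.flatnonzero(vs[1:] > vs[:-1])  # split after position i
        if len(cut) == 0:
            continue
        c1 = np.cumsum(ys)
        n1_total = c1[-1]
        n_left = cut + 1
        n_right = n - n_left
        l1 = c1[cut].astype(float)
        l0 = n_left - l1
        r1 = n1_total - l1
        r0 = n_right - r1
        gini_l = 1.0 - (l0 ** 2 + l1 ** 2) / n_left ** 2
        gini_r = 1.0 - (r0 ** 2 + r1 ** 2) / n_right ** 2
        gain = parent_impurity - (n_left * gini_l + n_right * gini_r) / n
        j = int(np.argmax(gain))  # first maximum -> lowest threshold
        if gain[j] > 1e-12 and (best is None or gain[j] > best[0] + 1e-12):
            thr = 0.5 * (vs[cut[j]] + vs[cut[j] + 1])
            best = (float(gain[j]), int(f), float(thr))
    return best


def grow_tree(X, y, max_depth=None, max_features=None,
              rng: np.random.Generator | None = None) -> Tree:
    """Grow a single CART tree by recursive best-Gini-split search.

    At each node a random subset of features (per ``max_features``) is
    scanned; growth stops on purity, on reaching ``max_depth``, or when no
    split decreases impurity.  Deterministic given the generator state.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=np.intp)
    if len(X) == 0:
        raise ValueError("cannot grow a tree on zero samples")
    if rng is None:
        rng = np.random.default_rng(0)
    n_features = X.shape[1]
    m = _n_candidate_features(max_features, n_features)

    feature, threshold, left, right, value, impurity = [], [], [], [], [], []

    def new_node(idx):
        counts = np.bincount(y[idx], minlength=2).astype(float)
        feature.append(LEAF)
        threshold.append(np.nan)
        left.append(-1)
        right.append(-1)
        value.append(counts)
        impurity.append(gini_impurity(counts))
        return len(feature) - 1

    # explicit stack keeps node ids in preorder and avoids recursion limits
    root_idx = np.arange(len(X))
    stack = [(new_node(root_idx), root_idx, 0)]
    while stack:
        node, idx, depth = stack.pop()
        counts = value[node]
        if counts[0] == 0 or counts[1] == 0:
            continue  # pure
        if max_depth is not None and depth >= max_depth:
            continue
        if m < n_features:
            cand = rng.choice(n_features, size=m, replace=False)
        else:
            cand = np.arange(n_features)
        split = _best_split(X, y, idx, cand, impurity[node])
        if split is None:
            continue
        _, f, thr = split
        go_left = X[idx, f] <= thr
        li = new_node(idx[go_left])
        ri = new_node(idx[~go_left])
        feature[node] = f
        threshold[node] = thr
        left[node] = li
        right[node] = ri
        stack.append((ri, idx[~go_left], depth + 1))
        stack.append((li, idx[go_left], depth + 1))

    return Tree(
        feature=np.asarray(feature, dtype=np.intp),
        threshold=np.asarray(threshold, dtype=float),
        left=np.asarray(left, dtype=np.intp),
        right=np.asarray(right, dtype=np.intp),
        value=np.asarray(value, dtype=float),
        impurity=np.asarray(impurity, dtype=float),
    )


@dataclass(frozen=True)
class ForestParams:
    """Hyperparameters of a forest fit.

    ``max_features`` accepts "sqrt", "log2", a fraction in (0, 1], an integer
    count, or None (all features).
    """

    n_estimators: int = 500
    max_depth: int | None = 10
    max_features: object = "sqrt"
    bootstrap: bool = True

    def to_dict(self) -> dict:
        return {
            "n_estimators": self.n_estimators,
            "max_depth": self.max_depth,
            "max_features": self.max_features,
            "bootstrap": self.bootstrap,
        }


@dataclass
class ForestModel:
    """A fitted bag of trees plus everything needed to reproduce it."""

    trees: list
    params: ForestParams
    feature_order: tuple
    seed: int
    class_order: tuple = (0, 1)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "params": self.params.to_dict(),
                    "feature_order": list(self.feature_order),
                    "seed": self.seed,
                    "class_order": list(self.class_order),
                    "trees": [t.to_dict() for t in self.trees],
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "ForestModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            trees=[Tree.from_dict(t) for t in d["trees"]],
            params=ForestParams(**d["params"]),
            feature_order=tuple(d["feature_order"]),
            seed=int(d["seed"]),
            class_order=tuple(d["class_order"]),
        )


def _as_array(X, feature_order):
    """Align X (DataFrame or array) to the model's feature order."""
    if isinstance(X, pd.DataFrame):
        missing = [f for f in feature_order if f not in X.columns]
        if missing:
            raise KeyError(f"features missing from input: {missing}")
        return X.loc[:, list(feature_order)].to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(feature_order):
        raise ValueError(
            f"expected {len(feature_order)} feature columns, got {X.shape[1]}"
        )
    return X


def fit_forest(X, y, params: ForestParams = ForestParams(),
               seed: int = 0, feature_order=None) -> ForestModel:
    """Fit a bagged forest: per-tree bootstrap (n draws with replacement) and
    per-node feature subsampling, all seeded through one SeedSequence."""
    if isinstance(X, pd.DataFrame):
        feature_order = tuple(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if feature_order is None:
            feature_order = tuple(range(X.shape[1]))
    y = np.asarray(y, dtype=np.intp)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in y")

    streams = np.random.SeedSequence(seed).spawn(params.n_estimators)
    trees = []
    n = len(X)
    for ss in streams:
        rng = np.random.default_rng(ss)
        if params.bootstrap:
            idx = rng.integers(0, n, size=n)
        else:
            idx = np.arange(n)
        trees.append(
            grow_tree(X[idx], y[idx], max_depth=params.max_depth,
                      max_features=params.max_features, rng=rng)
        )
    return ForestModel(trees=trees, params=params,
                       feature_order=tuple(feature_order), seed=seed)


def predict_proba(model: ForestModel, X) -> np.ndarray:
    """Mean over trees of each leaf's class-1 sample fraction."""
    arr = _as_array(X, model.feature_order)
    probs = np.zeros(len(arr))
    for tree in model.trees:
        probs += tree.predict_proba(arr)
    return probs / len(model.trees)


def predict(model: ForestModel, X, threshold: float = 0.5) -> np.ndarray:
    return (predict_proba(model, X) >= threshold).astype(int)


def gini_importance(model: ForestModel) -> pd.DataFrame:
    """Mean decrease in impurity per feature, averaged over trees.

    Each internal node contributes ``(n_node / n_root) * [imp(node) -
    weighted child impurities]`` to its split feature; per-tree totals are
    averaged over the forest and normalized to sum to one.  A forest with no
    splits at all returns all-zero importances (flagged via the ``any_split``
    attribute on the frame).
    """
    totals = np.zeros(len(model.feature_order))
    for tree in model.trees:
        n_root = tree.value[0].sum()
        internal = np.flatnonzero(tree.feature != LEAF)
        for node in internal:
            n = tree.value[node].sum()
            nl = tree.value[tree.left[node]].sum()
            nr = tree.value[tree.right[node]].sum()
            drop = tree.impurity[node] - (
                nl * tree.impurity[tree.left[node]]
                + nr * tree.impurity[tree.right[node]]
            ) / n
            totals[tree.feature[node]] += (n / n_root) * drop
    totals /= len(model.trees)
    any_split = totals.sum() > 0
    if any_split:
        totals = totals / totals.sum()
    out = pd.DataFrame(
        {"family": list(model.feature_order), "importance": totals}
    )
    # rank 1 = most important; ties broken by family identifier for stability
    out = out.sort_values(
        ["importance", "family"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    out.attrs["any_split"] = bool(any_split)
    return out


def select_top_features(X, y, n_select: int,
                        params: ForestParams = ForestParams(),
                        seed: int = 0) -> list:
    """The ``n_select`` families with highest Gini importance of a forest fit
    on (X, y); ties broken by family identifier."""
    if isinstance(X, pd.DataFrame):
        n_features = X.shape[1]
    else:
        n_features = np.asarray(X).shape[1]
    if n_select > n_features:
        raise ValueError("n_select exceeds the number of features")
    model = fit_forest(X, y, params=params, seed=seed)
    imp = gini_importance(model)
    return imp["family"].head(n_select).tolist()


def _param_sort_key(p: ForestParams):
    # "smaller model first": fewer trees, then shallower (None = unbounded)
    depth = math.inf if p.max_depth is None else p.max_depth
    return (p.n_estimators, depth)


def grid_search(X, y, folds, grid: dict, seed: int = 0,
                return_oof: bool = False):
    """Exhaustive hyperparameter search scored by mean cross-validation F1.

    ``folds`` is a list of index arrays (validation rows per fold) over the
    rows of X; ``grid`` maps any of {n_estimators, max_depth, max_features}
    to candidate lists.  Ties on mean F1 prefer the smaller model (fewer
    trees, then shallower).  Returns ``(best_params, cv_table)``, plus the
    winning cell's pooled out-of-fold probability scores when
    ``return_oof`` (they are exactly the validation predictions a refit
    with the same seed and folds would produce).
    """
    from .metrics import f1_score

    if isinstance(X, pd.DataFrame):
        X_arr = X.to_numpy(dtype=float)
        feature_order = tuple(X.columns)
    else:
        X_arr = np.asarray(X, dtype=float)
        feature_order = tuple(range(X_arr.shape[1]))
    y = np.asarray(y, dtype=np.intp)

    keys = sorted(grid)
    if not keys:
        raise ValueError("grid must not be empty")
    cells = [
        ForestParams(**dict(zip(keys, combo)))
        for combo in itertools.product(*(grid[k] for k in keys))
    ]
    all_idx = np.arange(len(X_arr))
    rows = []
    best = None  # (key, params, oof_scores)
    for params in cells:
        f1s = []
        oof = np.full(len(X_arr), np.nan)
        for fold in folds:
            val = np.asarray(fold)
            train = np.setdiff1d(all_idx, val)
            model = fit_forest(X_arr[train], y[train], params=params,
                               seed=seed, feature_order=feature_order)
            p = predict_proba(model, X_arr[val])
            oof[val] = p
            f1s.append(f1_score(y[val], (p >= 0.5).astype(int)))
        score = float(np.mean(f1s))
        rows.append({**params.to_dict(), "mean_cv_f1": score})
        key = (-score, *_param_sort_key(params))
        if best is None or key < best[0]:
            best = (key, params, oof)
    table = pd.DataFrame(rows)
    if return_oof:
        return best[1], table, best[2]
    return best[1], table
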