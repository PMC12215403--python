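"""Exact Shapley attribution for forest predictions.

Two routes to the same numbers:

* :func:`shap_bruteforce` — the classic Shapley definition, enumerating all
  2^m coalitions of the features the model actually uses, with the value of
  a coalition defined by the path-dependent conditional expectation
  (:func:`tree_expected_value`).  Exponential; the correctness oracle.
* :func:`shap_tree` — the polynomial-time path-dependent TreeSHAP recursion
  (extend/unwind over weighted feature paths), which equals the brute force
  wherever the latter is tractable.

Attributions are on the probability scale (leaf class-1 fractions); for every
explained instance ``base_value + sum(phi) == predicted probability`` (local
accuracy), features untouched by every tree get exactly zero (dummy axiom),
and forest attributions are the average of per-tree attributions (linearity).
Positive values push a species toward the resistant class.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forest import LEAF, ForestModel, Tree, predict_proba, _as_array

__all__ = [
    "ShapMatrix",
    "tree_expected_value",
    "shap_bruteforce",
    "shap_tree",
    "shap_vs_count",
]

BRUTEFORCE_MAX_FEATURES = 20


@dataclass
class ShapMatrix:
    """Per-species, per-family Shapley values for one model.

    ``phi`` is species x families (model feature set); ``base_value`` is the
    expected model output (the training-weighted mean prediction); for every
    species ``base_value + phi.sum(axis=1)`` equals ``model_output``.
    """

    phi: pd.DataFrame
    base_value: float
    model_output: pd.Series

    def local_accuracy_error(self) -> float:
        return float(
            np.abs(self.base_value + self.phi.sum(axis=1) - self.model_output).max()
        )

    def to_tsv(self, path) -> None:
        out = self.phi.copy()
        out["base_value"] = self.base_value
        out["model_output"] = self.model_output
        out.to_csv(path, sep="\t", index_label="species")


def _used_features(tree: Tree) -> set:
    return set(tree.feature[tree.feature != LEAF].tolist())


def model_used_features(model: ForestModel) -> list:
    used: set = set()
    for tree in model.trees:
        used |= _used_features(tree)
    return sorted(used)


def tree_expected_value(tree: Tree, x: np.ndarray, S) -> float:
    """Path-dependent conditional expectation of one tree.

    Descend from the root; at a node splitting on a feature in ``S`` follow
    the branch ``x`` takes, otherwise average both children weighted by their
    training sample counts.  ``S`` is a set of feature indices; the empty set
    gives the training-weighted mean leaf value.
    """
    S = set(S)

    def walk(node: int) -> float:
        f = tree.feature[node]
        if f == LEAF:
            return tree.leaf_probability(node)
        if f in S:
            child = tree.left[node] if x[f] <= tree.threshold[node] else tree.right[node]
            return walk(child)
        nl = tree.value[tree.left[node]].sum()
        nr = tree.value[tree.right[node]].sum()
        return (nl * walk(tree.left[node]) + nr * walk(tree.right[node])) / (nl + nr)

    return walk(0)


def shap_bruteforce(model: ForestModel, x) -> tuple[np.ndarray, float]:
    """Shapley values by direct coalition enumeration (the oracle).

    ``v(S)`` is the mean over trees of :func:`tree_expected_value`; features
    no tree uses are dummies (their value is exactly 0 and they are excluded
    from the enumeration, which is valid because they never change ``v``).
    Limited to models using at most 20 distinct features.
    """
    x = np.asarray(x, dtype=float)
    used = model_used_features(model)
    m = len(used)
    if m > BRUTEFORCE_MAX_FEATURES:
        raise ValueError(
            f"model uses {m} features; brute force is limited to "
            f"{BRUTEFORCE_MAX_FEATURES} — use shap_tree instead"
        )

    cache: dict[frozenset, float] = {}

    def v(S: frozenset) -> float:
        if S not in cache:
            cache[S] = float(
                np.mean([tree_expected_value(t, x, S) for t in model.trees])
            )
        return cache[S]

    phi = np.zeros(len(model.feature_order))
    fact = math.factorial
    for i in used:
        others = [f for f in used if f != i]
        total = 0.0
        for r in range(m):
            w = fact(r) * fact(m - r - 1) / fact(m)
            for S in itertools.combinations(others, r):
                fs = frozenset(S)
                total += w * (v(fs | {i}) - v(fs))
        phi[i] = total
    return phi, v(frozenset())


# ---------------------------------------------------------------------------
# Path-dependent TreeSHAP (extend / unwind over weighted paths)
# ---------------------------------------------------------------------------


class _Path:
    """The weighted path of unique features from the root to the current node."""

    __slots__ = ("d", "z", "o", "w")

    def __init__(self, capacity: int):
        self.d = np.empty(capacity, dtype=np.intp)  # feature index
        self.z = np.empty(capacity, dtype=float)  # fraction of zero (hidden) paths
        self.o = np.empty(capacity, dtype=float)  # fraction of one (followed) paths
        self.w = np.empty(capacity, dtype=float)  # permutation weight

    def copy_from(self, other: "_Path", length: int) -> None:
        self.d[:length] = other.d[:length]
        self.z[:length] = other.z[:length]
        self.o[:length] = other.o[:length]
        self.w[:length] = other.w[:length]


def _extend(p: _Path, depth: int, pz: float, po: float, pi: int) -> None:
    p.d[depth] = pi
    p.z[depth] = pz
    p.o[depth] = po
    p.w[depth] = 1.0 if depth == 0 else 0.0
    for i in range(depth - 1, -1, -1):
        p.w[i + 1] += po * p.w[i] * (i + 1) / (depth + 1)
        p.w[i] = pz * p.w[i] * (depth - i) / (depth + 1)


def _unwind(p: _Path, depth: int, idx: int) -> None:
    one = p.o[idx]
    zero = p.z[idx]
    nxt = p.w[depth]
    for i in range(depth - 1, -1, -1):
        if one != 0:
            tmp = p.w[i]
            p.w[i] = nxt * (depth + 1) / ((i + 1) * one)
            nxt = tmp - p.w[i] * zero * (depth - i) / (depth + 1)
        else:
            p.w[i] = p.w[i] * (depth + 1) / (zero * (depth - i))
    for i in range(idx, depth):
        p.d[i] = p.d[i + 1]
        p.z[i] = p.z[i + 1]
        p.o[i] = p.o[i + 1]


def _unwound_sum(p: _Path, depth: int, idx: int) -> float:
    one = p.o[idx]
    zero = p.z[idx]
    nxt = p.w[depth]
    total = 0.0
    for i in range(depth - 1, -1, -1):
        if one != 0:
            tmp = nxt * (depth + 1) / ((i + 1) * one)
            total += tmp
            nxt = p.w[i] - tmp * zero * (depth - i) / (depth + 1)
        else:
            total += p.w[i] / (zero * (depth - i) / (depth + 1))
    return total


def _tree_shap_single(tree: Tree, x: np.ndarray, phi: np.ndarray) -> None:
    max_path = tree.depth() + 2

    def recurse(node: int, depth: int, parent: _Path,
                pz: float, po: float, pi: int) -> None:
        p = _Path(max_path)
        p.copy_from(parent, depth)
        _extend(p, depth, pz, po, pi)
        f = tree.feature[node]
        if f == LEAF:
            leaf_value = tree.leaf_probability(node)
            for i in range(1, depth + 1):
                w = _unwound_sum(p, depth, i)
                phi[p.d[i]] += w * (p.o[i] - p.z[i]) * leaf_value
            return
        n = tree.value[node].sum()
        if x[f] <= tree.threshold[node]:
            hot, cold = tree.left[node], tree.right[node]
        else:
            hot, cold = tree.right[node], tree.left[node]
        hot_frac = tree.value[hot].sum() / n
        cold_frac = tree.value[cold].sum() / n

        iz, io = 1.0, 1.0
        path_idx = -1
        for i in range(1, depth + 1):
            if p.d[i] == f:
                path_idx = i
                break
        if path_idx >= 0:
            iz, io = p.z[path_idx], p.o[path_idx]
            _unwind(p, depth, path_idx)
            depth -= 1
        recurse(hot, depth + 1, p, iz * hot_frac, io, f)
        recurse(cold, depth + 1, p, iz * cold_frac, 0.0, f)

    recurse(0, 0, _Path(max_path), 1.0, 1.0, -1)


def _phi_single_tree(tree: Tree, x: np.ndarray, n_features: int) -> np.ndarray:
    # phi indexed by feature id; slot -1 would be the root placeholder but the
    # leaf loop starts at path position 1, so it is never touched.
    phi = np.zeros(n_features)
    _tree_shap_single(tree, x, phi)
    return phi


def shap_tree(model: ForestModel, X) -> ShapMatrix:
    """Exact path-dependent Shapley values for every row of ``X``.

    Per-tree attributions are averaged over the forest (the model output is
    the mean of tree outputs) and the base value is the mean of the trees'
    training-weighted mean leaf values.
    """
    arr = _as_array(X, model.feature_order)
    n_features = len(model.feature_order)
    n_trees = len(model.trees)

    base = float(
        np.mean([tree_expected_value(t, arr[0], frozenset()) for t in model.trees])
    )
    phi = np.zeros((len(arr), n_features))
    for i, x in enumerate(arr):
        acc = np.zeros(n_features)
        for tree in model.trees:
            acc += _phi_single_tree(tree, x, n_features)
        phi[i] = acc / n_trees

    index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(len(arr))
    return ShapMatrix(
        phi=pd.DataFrame(phi, index=index, columns=list(model.feature_order)),
        base_value=base,
        model_output=pd.Series(predict_proba(model, X), index=index),
    )


def shap_vs_count(shap: ShapMatrix, counts: pd.DataFrame, family) -> dict:
    """Pair each species' gene count with its Shapley value for one family.

    Returns the paired table plus the minimal separating count ``c*`` such
    that ``phi > 0`` exactly for species with ``count >= c*`` — the pattern
    where owning at least ``c*`` copies pushes a species toward resistance.
    ``c*`` is ``None`` when no such threshold exists (including the all-zero
    case, which is flagged separately).
    """
    if family not in shap.phi.columns:
        raise KeyError(f"family {family!r} not among the model features")
    if family not in counts.columns:
        raise KeyError(f"family {family!r} not in the count matrix")
    common = shap.phi.index.intersection(counts.index)
    table = pd.DataFrame(
        {
            "count": counts.loc[common, family].astype(int),
            "phi": shap.phi.loc[common, family],
        }
    ).sort_index()

    all_zero = bool(np.all(table["phi"] == 0))
    c_star = None
    if not all_zero:
        candidates = sorted(table["count"].unique())
        for c in candidates:
            above = table.loc[table["count"] >= c, "phi"]
            below = table.loc[table["count"] < c, "phi"]
            if len(above) and np.all(above > 0) and np.all(below <= 0):
                c_star = int(c)
                break
    return {"table": table, "separating_count": c_star, "all_zero": all_zero}
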