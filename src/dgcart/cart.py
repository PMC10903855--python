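"""Binary classification and regression trees grown from scratch.

Two trees serve the two goals of post-stratified estimation: a
classification tree on the stratum-membership indicators (Gini impurity,
majority-vote leaf labels) and a regression tree on the study variable
(within-node variance impurity, leaf-mean prediction).  Growth is standard
greedy recursive partitioning with the usual node gates (``min_split``,
``min_bucket``, ``max_depth``), an rpart-style complexity parameter ``cp``
(a split is kept only when it lowers the tree's total impurity by at least
``cp`` times the root impurity), and a variance-reduction stopping
threshold ``delta_o``: splitting continues only while the largest
per-stratum (or, for regression, the overall) reduction in pooled variance
across the tree partition stays at or above ``delta_o``.

Determinism: numeric cuts are placed at midpoints between consecutive
distinct sorted values; ties in gain are broken by lowest covariate index,
then lowest threshold.  Categorical covariates are handled by the classical
CART reduction — categories are ordered by their within-category outcome
mean (regression) or by their share of the node's majority stratum
(classification) and then scanned as if ordered.  A category level unseen
during training is routed to the child that received more training rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

_EPS = 1e-12


@dataclass(frozen=True)
class TreeSpec:
    """Hyper-parameters controlling tree growth.

    min_split
        Minimum node size for a split to be attempted.
    max_depth
        Maximum depth of any node (root = 0); ``None`` means unbounded.
    min_bucket
        Minimum number of training rows in each child of a split.
    cp
        Complexity parameter: minimum reduction of the tree's total
        impurity, as a fraction of the root impurity, for a split to be kept.
    delta_o
        Pre-specified variance-reduction stopping threshold; 0 disables it.
    n_trees
        Number of trees when the spec seeds a forest; 1 for a single tree.
    """

    min_split: int = 2
    max_depth: int | None = None
    min_bucket: int = 1
    cp: float = 0.0
    delta_o: float = 0.0
    n_trees: int = 1

    def __post_init__(self) -> None:
        if self.min_split < 1:
            raise ValueError(f"min_split must be >= 1, got {self.min_split}")
        if self.min_bucket < 1:
            raise ValueError(f"min_bucket must be >= 1, got {self.min_bucket}")
        if self.min_bucket > self.min_split:
            raise ValueError(
                f"min_bucket ({self.min_bucket}) must not exceed min_split ({self.min_split})"
            )
        if self.max_depth is not None and self.max_depth < 0:
            raise ValueError(f"max_depth must be >= 0 or None, got {self.max_depth}")
        if self.cp < 0 or self.delta_o < 0:
            raise ValueError("cp and delta_o must be non-negative")
        if self.n_trees < 1:
            raise ValueError(f"n_trees must be >= 1, got {self.n_trees}")


# ---------------------------------------------------------------------------
# impurity measures


def gini_impurity(class_counts: Sequence[float]) -> float:
    """Gini index 1 - sum_h (n_h/n)^2 of a node's class counts."""
    counts = np.asarray(class_counts, dtype=float)
    if counts.size == 0 or np.any(counts < 0):
        raise ValueError("class counts must be non-negative and non-empty")
    n = counts.sum()
    if n == 0:
        raise ValueError("at least one class count must be positive")
    p = counts / n
    return float(1.0 - np.sum(p * p))


def variance_impurity(values: Sequence[float]) -> float:
    """Mean squared deviation from the node mean (divisor = node size)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("values must be non-empty")
    return float(np.mean((v - v.mean()) ** 2))


def delta_variation(
    parent_partition: Sequence[np.ndarray],
    child_partition: Sequence[np.ndarray],
    values: Sequence[float],
) -> float:
    """Reduction in pooled within-block variance from refining a partition.

    Both partitions are given as sequences of index arrays into ``values``;
    the child partition must refine the parent one.  ``values`` is the
    quantity whose variance the stopping rule watches — the 0/1 membership
    indicator of a stratum for classification trees (block variance
    lambda(1-lambda)) or the outcome for regression trees.  The pooled
    variance of a partition is the size-weighted mean of within-block
    population variances; refinement can only lower it, so the returned
    reduction is >= 0.
    """
    values = np.asarray(values, dtype=float)

    def _check(partition: Sequence[np.ndarray]) -> list[np.ndarray]:
        blocks = [np.asarray(b, dtype=int) for b in partition]
        flat = np.concatenate(blocks) if blocks else np.array([], dtype=int)
        if len(flat) != len(values) or len(np.unique(flat)) != len(values):
            raise ValueError("partition blocks must cover every index exactly once")
        return blocks

    parent = _check(parent_partition)
    child = _check(child_partition)

    owner = np.empty(len(values), dtype=int)
    for i, block in enumerate(parent):
        owner[block] = i
    for block in child:
        if block.size and len(np.unique(owner[block])) != 1:
            raise ValueError("child partition does not refine the parent partition")

    def _pooled(blocks: list[np.ndarray]) -> float:
        n = len(values)
        return sum(
            (len(b) / n) * float(np.var(values[b])) for b in blocks if len(b) > 0
        )

    return _pooled(parent) - _pooled(child)


# ---------------------------------------------------------------------------
# column preparation

_NUM = "num"
_CAT = "cat"


def _prepare_columns(X: Any) -> tuple[list[str], list[str], list[np.ndarray]]:
    """Split a DataFrame/array into per-column arrays tagged num/cat."""
    if isinstance(X, pd.DataFrame):
        names, kinds, cols = [], [], []
        for name in X.columns:
            s = X[name]
            names.append(str(name))
            if pd.api.types.is_numeric_dtype(s) and not isinstance(
                s.dtype, pd.CategoricalDtype
            ):
                kinds.append(_NUM)
                cols.append(s.to_numpy(dtype=float))
            else:
                kinds.append(_CAT)
                cols.append(s.astype(object).to_numpy())
        return names, kinds, cols
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr.reshape(-1, 1)
    names = [f"x{j + 1}" for j in range(arr.shape[1])]
    return names, [_NUM] * arr.shape[1], [arr[:, j] for j in range(arr.shape[1])]


# ---------------------------------------------------------------------------
# split representation and search


@dataclass
class Split:
    """An admissible binary split together with its impurity gain.

    ``gain`` is the node-local impurity decrease: parent impurity minus the
    size-weighted mean of the child impurities.  For numeric features rows
    with value <= ``threshold`` go left; for categorical features rows whose
    level is in ``left_categories`` go left.
    """

    feature: int
    threshold: float | None
    left_categories: frozenset | None
    right_categories: frozenset | None
    gain: float
    left_mask: np.ndarray


def _scan_ordered(
    v: np.ndarray,
    target: np.ndarray,
    criterion: str,
    n_classes: int,
    min_bucket: int,
) -> tuple[int, float] | None:
    """Best boundary on an ordered feature; returns (left size, child impurity).

    ``v`` must be sorted ascending with ``target`` aligned.  Candidates are
    boundaries between distinct consecutive values satisfying min_bucket on
    both sides; ties in impurity go to the smallest left size (lowest cut).
    """
    n = len(v)
    ks = np.flatnonzero(v[1:] > v[:-1]) + 1
    ks = ks[(ks >= min_bucket) & (ks <= n - min_bucket)]
    if ks.size == 0:
        return None
    nl = ks.astype(float)
    nr = n - nl
    if criterion == "gini":
        onehot = np.zeros((n, n_classes))
        onehot[np.arange(n), target.astype(int)] = 1.0
        cum = np.cumsum(onehot, axis=0)
        L = cum[ks - 1]
        R = cum[-1] - L
        child = (
            nl * (1.0 - (L * L).sum(axis=1) / (nl * nl))
            + nr * (1.0 - (R * R).sum(axis=1) / (nr * nr))
        ) / n
    else:
        s1 = np.cumsum(target)
        s2 = np.cumsum(target * target)
        sse_l = s2[ks - 1] - s1[ks - 1] ** 2 / nl
        sse_r = (s2[-1] - s2[ks - 1]) - (s1[-1] - s1[ks - 1]) ** 2 / nr
        child = (sse_l + sse_r) / n
    best = child.min()
    k = int(ks[np.flatnonzero(child <= best + _EPS)[0]])
    return k, float(best)


def _order_categories(
    col: np.ndarray, target: np.ndarray, criterion: str, n_classes: int
) -> list:
    """CART category ordering: by outcome mean or majority-stratum share."""
    cats = sorted(set(col.tolist()), key=repr)
    if criterion == "gini":
        counts = np.zeros(n_classes)
        for c in target.astype(int):
            counts[c] += 1
        major = int(np.argmax(counts))
        stat = {
            c: float(np.mean(target[col == c] == major)) for c in cats
        }
    else:
        stat = {c: float(np.mean(target[col == c])) for c in cats}
    return sorted(cats, key=lambda c: (stat[c], repr(c)))


def _search_node(
    cols: list[np.ndarray],
    kinds: list[str],
    idx: np.ndarray,
    target: np.ndarray,
    criterion: str,
    n_classes: int,
    min_bucket: int,
    features: Sequence[int] | None = None,
) -> Split | None:
    """Best admissible split over the given features at node ``idx``."""
    t = target[idx]
    best: Split | None = None
    feats = range(len(cols)) if features is None else features
    for j in feats:
        v = cols[j][idx]
        if kinds[j] == _NUM:
            order = np.argsort(v, kind="stable")
            hit = _scan_ordered(v[order], t[order], criterion, n_classes, min_bucket)
            if hit is None:
                continue
            k, child_imp = hit
            vs = v[order]
            thr = 0.5 * (vs[k - 1] + vs[k])
            if thr >= vs[k]:  # guard against midpoint rounding up
                thr = float(vs[k - 1])
            cand = Split(j, float(thr), None, None, -child_imp, v <= thr)
        else:
            ordered = _order_categories(v, t, criterion, n_classes)
            rank = {c: r for r, c in enumerate(ordered)}
            rv = np.array([rank[c] for c in v.tolist()], dtype=float)
            order = np.argsort(rv, kind="stable")
            hit = _scan_ordered(rv[order], t[order], criterion, n_classes, min_bucket)
            if hit is None:
                continue
            k, child_imp = hit
            cut_rank = rv[order][k - 1]
            left = frozenset(c for c in ordered if rank[c] <= cut_rank)
            right = frozenset(c for c in ordered if rank[c] > cut_rank)
            cand = Split(
                j, None, left, right, -child_imp,
                np.array([c in left for c in v.tolist()]),
            )
        if best is None or cand.gain > best.gain + _EPS:
            best = cand
    if best is None:
        return None
    # convert stored -child_impurity into a true gain
    parent = (
        gini_impurity(np.bincount(t.astype(int), minlength=n_classes))
        if criterion == "gini"
        else variance_impurity(t)
    )
    best.gain = parent + best.gain
    return best


def best_split(
    X: Any,
    target: Sequence[float],
    criterion: str,
    spec: TreeSpec = TreeSpec(),
) -> Split | None:
    """Best admissible (covariate, cut) for one node, or None.

    Applies ``min_split``, ``min_bucket`` and — treating the node as its own
    root — the ``cp`` gate.  Absence of an admissible improving split is a
    valid None return, not an error.
    """
    if criterion not in ("gini", "variance"):
        raise ValueError(f"criterion must be 'gini' or 'variance', got {criterion!r}")
    names, kinds, cols = _prepare_columns(X)
    target = np.asarray(target)
    n = len(target)
    if n < 2 or n < spec.min_split:
        return None
    if criterion == "gini":
        classes = np.array(sorted(set(target.tolist())))
        enc = np.searchsorted(classes, target)
        parent = gini_impurity(np.bincount(enc, minlength=len(classes)))
        t = enc.astype(float)
        n_classes = len(classes)
    else:
        t = np.asarray(target, dtype=float)
        parent = variance_impurity(t)
        n_classes = 0
    if parent <= _EPS:
        return None
    sp = _search_node(
        cols, kinds, np.arange(n), t, criterion, n_classes, spec.min_bucket
    )
    if sp is None or sp.gain <= _EPS:
        return None
    if sp.gain + _EPS < spec.cp * parent:
        return None
    return sp


# ---------------------------------------------------------------------------
# fitted trees


@dataclass
class Node:
    """One node of a fitted tree; a leaf when ``left`` is None."""

    id: int
    depth: int
    n: int
    impurity: float
    feature: int | None = None
    threshold: float | None = None
    left_categories: frozenset | None = None
    right_categories: frozenset | None = None
    left: int | None = None
    right: int | None = None
    class_counts: np.ndarray | None = None
    label: int | None = None
    mean: float | None = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None


@dataclass
class FittedTree:
    """A grown binary tree plus the training metadata needed to apply it."""

    kind: str  # "classification" | "regression"
    nodes: list[Node]
    feature_names: list[str]
    feature_kinds: list[str]
    classes: np.ndarray | None
    n_train: int
    root_impurity: float

    @property
    def n_leaves(self) -> int:
        return sum(1 for nd in self.nodes if nd.is_leaf)

    @property
    def depth(self) -> int:
        return max(nd.depth for nd in self.nodes)

    def apply(self, X: Any) -> np.ndarray:
        """Leaf node id for every row of X."""
        names, kinds, cols = _prepare_columns(X)
        if len(cols) != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} covariates, got {len(cols)}"
            )
        nrows = len(cols[0]) if cols else 0
        out = np.empty(nrows, dtype=int)

        def route(node_id: int, idx: np.ndarray) -> None:
            nd = self.nodes[node_id]
            if nd.is_leaf:
                out[idx] = nd.id
                return
            if nd.threshold is not None:
                mask = cols[nd.feature][idx] <= nd.threshold
            else:
                vals = cols[nd.feature][idx]
                left_set, right_set = nd.left_categories, nd.right_categories
                mask = np.empty(len(idx), dtype=bool)
                for i, val in enumerate(vals.tolist()):
                    if val in left_set:
                        mask[i] = True
                    elif val in right_set:
                        mask[i] = False
                    else:  # unseen level: child with more training rows
                        mask[i] = (
                            self.nodes[nd.left].n >= self.nodes[nd.right].n
                        )
            route(nd.left, idx[mask])
            route(nd.right, idx[~mask])

        if nrows:
            route(0, np.arange(nrows))
        return out

    def to_dict(self) -> dict:
        """JSON-serialisable structure of rules and leaf statistics."""
        nodes = []
        for nd in self.nodes:
            d: dict[str, Any] = {
                "id": nd.id,
                "depth": nd.depth,
                "n": nd.n,
                "impurity": nd.impurity,
            }
            if not nd.is_leaf:
                d["feature"] = self.feature_names[nd.feature]
                if nd.threshold is not None:
                    d["threshold"] = nd.threshold
                else:
                    d["left_categories"] = sorted(nd.left_categories, key=repr)
                    d["right_categories"] = sorted(nd.right_categories, key=repr)
                d["left"] = nd.left
                d["right"] = nd.right
            if nd.class_counts is not None:
                d["class_counts"] = [int(c) for c in nd.class_counts]
                d["label"] = int(nd.label)
            if nd.mean is not None:
                d["mean"] = nd.mean
            nodes.append(d)
        return {
            "kind": self.kind,
            "feature_names": self.feature_names,
            "feature_kinds": self.feature_kinds,
            "classes": None if self.classes is None else [int(c) for c in self.classes],
            "n_train": self.n_train,
            "root_impurity": self.root_impurity,
            "nodes": nodes,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


class _Grower:
    """Recursive tree builder shared by single trees and forests."""

    def __init__(
        self,
        cols: list[np.ndarray],
        kinds: list[str],
        names: list[str],
        target: np.ndarray,
        kind: str,
        spec: TreeSpec,
        classes: np.ndarray | None = None,
        mtry: int | None = None,
        rng: np.random.Generator | None = None,
    ) -> None:
        self.cols, self.kinds, self.names = cols, kinds, names
        self.target = target
        self.kind = kind
        self.criterion = "gini" if kind == "classification" else "variance"
        self.spec = spec
        self.classes = classes
        self.n_classes = 0 if classes is None else len(classes)
        self.mtry = mtry
        self.rng = rng
        self.root_n = len(target)
        self.nodes: list[Node] = []
        self.root_impurity = 0.0

    def _node_stats(self, idx: np.ndarray) -> tuple[float, np.ndarray | None, float]:
        t = self.target[idx]
        if self.kind == "classification":
            counts = np.bincount(t.astype(int), minlength=self.n_classes)
            return gini_impurity(counts), counts, float("nan")
        return variance_impurity(t), None, float(t.mean())

    def _feature_subset(self) -> Sequence[int] | None:
        if self.mtry is None or self.mtry >= len(self.cols):
            return None
        picked = self.rng.choice(len(self.cols), size=self.mtry, replace=False)
        return sorted(int(j) for j in picked)

    def _delta_ok(self, idx: np.ndarray, sp: Split, gain_total: float) -> bool:
        """Stopping rule: largest per-stratum (or overall) pooled-variance
        reduction across the tree partition must not fall below delta_o."""
        if self.spec.delta_o <= 0:
            return True
        if self.kind == "regression":
            return gain_total >= self.spec.delta_o - _EPS
        t = self.target[idx]
        n = len(idx)
        nl = int(sp.left_mask.sum())
        nr = n - nl
        best = 0.0
        for c in range(self.n_classes):
            a = (t == c).astype(float)
            vp = a.mean() * (1 - a.mean())
            vl = a[sp.left_mask].mean() * (1 - a[sp.left_mask].mean())
            vr = a[~sp.left_mask].mean() * (1 - a[~sp.left_mask].mean())
            red = (n / self.root_n) * (vp - (nl * vl + nr * vr) / n)
            best = max(best, red)
        return best >= self.spec.delta_o - _EPS

    def _majority_ok(self, idx: np.ndarray, sp: Split) -> bool:
        """Each child must keep >= 2 rows of its own majority stratum."""
        if self.kind != "classification":
            return True
        t = self.target[idx]
        for mask in (sp.left_mask, ~sp.left_mask):
            counts = np.bincount(t[mask].astype(int), minlength=self.n_classes)
            if counts.max() < 2:
                return False
        return True

    def grow(self) -> FittedTree:
        imp, _, _ = self._node_stats(np.arange(self.root_n))
        self.root_impurity = imp
        self._recurse(np.arange(self.root_n), 0)
        return FittedTree(
            kind=self.kind,
            nodes=self.nodes,
            feature_names=self.names,
            feature_kinds=self.kinds,
            classes=self.classes,
            n_train=self.root_n,
            root_impurity=self.root_impurity,
        )

    def _recurse(self, idx: np.ndarray, depth: int) -> int:
        imp, counts, mean = self._node_stats(idx)
        node = Node(id=len(self.nodes), depth=depth, n=len(idx), impurity=imp)
        if counts is not None:
            node.class_counts = counts
            node.label = int(self.classes[int(np.argmax(counts))])
        else:
            node.mean = mean
        self.nodes.append(node)

        spec = self.spec
        n = len(idx)
        can_split = (
            n >= max(spec.min_split, 2, 2 * spec.min_bucket)
            and imp > _EPS
            and (spec.max_depth is None or depth < spec.max_depth)
        )
        if not can_split:
            return node.id
        sp = _search_node(
            self.cols,
            self.kinds,
            idx,
            self.target,
            self.criterion,
            self.n_classes,
            spec.min_bucket,
            features=self._feature_subset(),
        )
        if sp is None or sp.gain <= _EPS:
            return node.id
        gain_total = (n / self.root_n) * sp.gain
        if gain_total + _EPS < spec.cp * self.root_impurity:
            return node.id
        if not self._delta_ok(idx, sp, gain_total):
            return node.id
        if not self._majority_ok(idx, sp):
            return node.id

        node.feature = sp.feature
        node.threshold = sp.threshold
        node.left_categories = sp.left_categories
        node.right_categories = sp.right_categories
        node.left = self._recurse(idx[sp.left_mask], depth + 1)
        node.right = self._recurse(idx[~sp.left_mask], depth + 1)
        return node.id


def _grow(
    X: Any,
    target: Sequence,
    kind: str,
    spec: TreeSpec,
    mtry: int | None,
    rng: np.random.Generator | None,
) -> FittedTree:
    names, kinds, cols = _prepare_columns(X)
    target = np.asarray(target)
    if len(target) < 2:
        raise ValueError(f"need at least 2 rows to grow a tree, got {len(target)}")
    if cols and any(len(c) != len(target) for c in cols):
        raise ValueError("covariates and target must have the same number of rows")
    if kind == "classification":
        classes = np.array(sorted(set(int(v) for v in target.tolist())))
        enc = np.searchsorted(classes, target).astype(float)
        grower = _Grower(cols, kinds, names, enc, kind, spec, classes, mtry, rng)
    else:
        grower = _Grower(
            cols, kinds, names, np.asarray(target, dtype=float), kind, spec, None,
            mtry, rng,
        )
    return grower.grow()


def grow_classification_tree(
    X: Any,
    labels: Sequence[int],
    spec: TreeSpec = TreeSpec(),
    *,
    mtry: int | None = None,
    rng: np.random.Generator | None = None,
) -> FittedTree:
    """Grow a classification tree on stratum-membership labels.

    Besides the spec gates, a split is rejected when either child would
    retain fewer than 2 sampled rows of its own majority stratum, so every
    leaf's label rests on at least two observations.
    """
    return _grow(X, labels, "classification", spec, mtry, rng)


def grow_regression_tree(
    X: Any,
    y: Sequence[float],
    spec: TreeSpec = TreeSpec(),
    *,
    mtry: int | None = None,
    rng: np.random.Generator | None = None,
) -> FittedTree:
    """Grow a regression tree on the study variable; leaves store means."""
    return _grow(X, y, "regression", spec, mtry, rng)


def classify_units(tree: FittedTree, X: Any) -> np.ndarray:
    """Majority-vote stratum label of each unit's leaf (ties: lowest label)."""
    if tree.kind != "classification":
        raise ValueError("classify_units requires a classification tree")
    leaf = tree.apply(X)
    lut = np.full(len(tree.nodes), -1, dtype=int)
    for nd in tree.nodes:
        if nd.is_leaf:
            lut[nd.id] = nd.label
    return lut[leaf]


def predict_values(tree: FittedTree, X: Any) -> np.ndarray:
    """Leaf-mean prediction of the study variable for each unit."""
    if tree.kind != "regression":
        raise ValueError("predict_values requires a regression tree")
    leaf = tree.apply(X)
    lut = np.full(len(tree.nodes), np.nan)
    for nd in tree.nodes:
        if nd.is_leaf:
            lut[nd.id] = nd.mean
    return lut[leaf]
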