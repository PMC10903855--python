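"""Bagged ensembles of double-goal trees.

A membership forest aggregates per-tree majority labels by plurality vote
(ties broken toward the lowest stratum index); an outcome forest averages
per-tree leaf-mean predictions.  Each tree is grown on a bootstrap resample
of the sampled rows (with replacement, at the sample size) considering
``mtry`` randomly chosen covariates per split.  Defaults follow forest
convention: ``mtry = floor(sqrt(p))`` for classification and
``floor(p/3)`` for regression, never below 1.

Per-tree randomness is derived from the forest seed by a counter scheme:
tree ``t`` uses ``default_rng(SeedSequence([seed, STREAM_FOREST, t]))``, so
ensembles are reproducible and individual trees re-derivable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .cart import FittedTree, TreeSpec, classify_units, predict_values, _prepare_columns
from .population import STREAM_FOREST


@dataclass(frozen=True)
class ForestSpec:
    """Forest hyper-parameters wrapped around a base :class:`TreeSpec`."""

    base: TreeSpec = TreeSpec(min_split=20, min_bucket=1, cp=0.001)
    n_trees: int = 500
    mtry: int | None = None
    bootstrap: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError(f"n_trees must be >= 1, got {self.n_trees}")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError(f"mtry must be >= 1, got {self.mtry}")


@dataclass
class TreeEnsemble:
    """A fitted forest: trees plus their in-bag row indices."""

    kind: str  # "classification" | "regression"
    trees: list[FittedTree]
    inbag: list[np.ndarray]
    n_train: int

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "n_trees": self.n_trees,
            "trees": [t.to_dict() for t in self.trees],
        }


def default_mtry(p: int, kind: str) -> int:
    """Conventional per-split covariate count: sqrt(p) or p/3, floored, >= 1."""
    if kind == "classification":
        return max(1, int(math.floor(math.sqrt(p))))
    return max(1, int(math.floor(p / 3)))


def grow_forest(
    X: Any,
    target: Sequence,
    kind: str,
    spec: ForestSpec,
) -> TreeEnsemble:
    """Grow ``n_trees`` bagged trees for membership or outcome prediction."""
    if kind not in ("classification", "regression"):
        raise ValueError(f"kind must be 'classification' or 'regression', got {kind!r}")
    from .cart import grow_classification_tree, grow_regression_tree

    target = np.asarray(target)
    n = len(target)
    if n < 2:
        raise ValueError(f"need at least 2 rows to grow a forest, got {n}")
    names, kinds, cols = _prepare_columns(X)
    p = len(cols)
    mtry = spec.mtry if spec.mtry is not None else default_mtry(p, kind)
    mtry = min(mtry, p) if p else None

    grow = grow_classification_tree if kind == "classification" else grow_regression_tree
    trees: list[FittedTree] = []
    inbag: list[np.ndarray] = []
    is_frame = hasattr(X, "iloc")
    for t in range(spec.n_trees):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(spec.seed), STREAM_FOREST, t])
        )
        if spec.bootstrap:
            rows = np.sort(rng.integers(0, n, size=n))
        else:
            rows = np.arange(n)
        Xt = X.iloc[rows] if is_frame else np.asarray(X)[rows]
        trees.append(grow(Xt, target[rows], spec.base, mtry=mtry, rng=rng))
        inbag.append(rows)
    return TreeEnsemble(kind=kind, trees=trees, inbag=inbag, n_train=n)


def forest_classify(ensemble: TreeEnsemble, X: Any) -> np.ndarray:
    """Plurality vote over per-tree labels; ties go to the lowest stratum."""
    if ensemble.kind != "classification":
        raise ValueError("forest_classify requires a classification ensemble")
    if ensemble.n_trees == 0:
        raise ValueError("empty ensemble")
    votes = np.stack([classify_units(t, X) for t in ensemble.trees])
    classes = np.unique(votes)
    counts = np.stack([(votes == c).sum(axis=0) for c in classes])
    return classes[np.argmax(counts, axis=0)]


def forest_predict(ensemble: TreeEnsemble, X: Any) -> np.ndarray:
    """Arithmetic mean of per-tree leaf-mean predictions."""
    if ensemble.kind != "regression":
        raise ValueError("forest_predict requires a regression ensemble")
    if ensemble.n_trees == 0:
        raise ValueError("empty ensemble")
    preds = np.stack([predict_values(t, X) for t in ensemble.trees])
    return preds.mean(axis=0)


def oob_misclassification(
    ensemble: TreeEnsemble, X: Any, labels: Sequence[int]
) -> float:
    """Out-of-bag error: vote over trees whose bootstrap missed each row.

    Rows that are in-bag for every tree are excluded from the rate.
    """
    if ensemble.kind != "classification":
        raise ValueError("oob_misclassification requires a classification ensemble")
    labels = np.asarray(labels)
    n = len(labels)
    votes = np.stack([classify_units(t, X) for t in ensemble.trees])
    inbag_mask = np.zeros((ensemble.n_trees, n), dtype=bool)
    for t, rows in enumerate(ensemble.inbag):
        inbag_mask[t, np.unique(rows)] = True
    classes = np.unique(votes)
    counts = np.zeros((len(classes), n))
    for ci, c in enumerate(classes):
        counts[ci] = ((votes == c) & ~inbag_mask).sum(axis=0)
    has_oob = (~inbag_mask).any(axis=0)
    if not has_oob.any():
        raise ValueError("no out-of-bag rows; is bootstrap disabled?")
    pred = classes[np.argmax(counts, axis=0)]
    return float(np.mean(pred[has_oob] != labels[has_oob]))
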