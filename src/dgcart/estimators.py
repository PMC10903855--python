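"""Stratum-specific total estimators and their model diagnostics.

The baseline is the expansion estimator

    t_hat_yhE = (N/n) * sum_{i in s} a_hi y_i = N * lambda_hat_h * ybar_h,

the best linear unbiased predictor of the stratum total under the
homogeneous superpopulation model without auxiliary variables; its model
variance of prediction error is ``N (N-n) sigma*_h^2 / n`` with
``sigma*_h^2 = lambda_h sigma_h^2 + lambda_h (1-lambda_h) mu_h^2``.

The tree-based (double-goal CART) estimator adds, to the sampled stratum
total, predictions for the non-sampled units that the classification tree
assigns to the stratum:

    T_hat_tbh = sum_{s} a_hi y_i + sum_{s-bar} a_hat_hi y_hat_i    (direct)

A smoothed algebraic variant replaces the raw prediction sum with the
combined stratum mean ybar*_h of the classified non-sampled units,

    T_hat_tbh = n lambda_hat_h (ybar_sh - ybar*_h) + lambda_hat_h N ybar*_h,

where ybar*_h averages, over non-sampled units classified into h, the
stratum-h conditional leaf means of the regression tree (the mean of the
sampled stratum-h outcomes routed to each leaf).  When classification does
not divide the data in a meaningful way — in particular with single-leaf
trees — ybar*_h collapses to ybar_sh and the smoothed estimator coincides
exactly with the expansion estimator.

Conditional-bias and prediction-error-variance diagnostics of the
tree-based estimator are reporting-only quantities and never feed back
into estimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Any, Sequence

import numpy as np

from .cart import FittedTree
from .forest import TreeEnsemble
from .population import SurveySample

VARIANTS = ("expansion", "dgcart_direct", "dgcart_combined", "dgcart_smoothed")


@dataclass
class DomainEstimate:
    """One stratum's estimate under one estimator variant."""

    stratum: int
    total_hat: float
    mean_hat: float
    lambda_hat: float
    variant: str
    model_variance: float | None = None


@dataclass(frozen=True)
class ModelMoments:
    """Superpopulation moments (lambda_h, mu_h, sigma_h^2) of one stratum."""

    lambda_h: float
    mu_h: float
    sigma2_h: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_h <= 1.0:
            raise ValueError(f"lambda_h must lie in [0, 1], got {self.lambda_h}")
        if self.sigma2_h < 0:
            raise ValueError(f"sigma2_h must be >= 0, got {self.sigma2_h}")

    @property
    def sigma_star_sq(self) -> float:
        """Variance of A_h Y: lambda sigma^2 + lambda (1-lambda) mu^2."""
        return (
            self.lambda_h * self.sigma2_h
            + self.lambda_h * (1.0 - self.lambda_h) * self.mu_h**2
        )


# ---------------------------------------------------------------------------
# expansion estimator


def _stratum_sample_mean(sample: SurveySample, h: int) -> tuple[float, int]:
    n_h = sample.n_h(h)
    if n_h == 0:
        warnings.warn(
            f"no sampled unit observed in stratum {h}; using the 0 convention",
            stacklevel=3,
        )
        return 0.0, 0
    return float(sample.y[sample.stratum == h].mean()), n_h


def expansion_total(sample: SurveySample, h: int) -> DomainEstimate:
    """Expansion estimator of the stratum-h total, N lambda_hat_h ybar_h."""
    if sample.n < 1:
        raise ValueError("sample is empty")
    ybar_h, n_h = _stratum_sample_mean(sample, h)
    total = (sample.N / sample.n) * float(sample.y[sample.stratum == h].sum())
    return DomainEstimate(
        stratum=h,
        total_hat=total,
        mean_hat=ybar_h,
        lambda_hat=n_h / sample.n,
        variant="expansion",
    )


def expansion_model_variance(moments: ModelMoments, N: int, n: int) -> float:
    """Model variance of the expansion estimator's prediction error."""
    if not 0 < n <= N:
        raise ValueError(f"need 0 < n <= N, got n={n}, N={N}")
    return N * (N - n) / n * moments.sigma_star_sq


# ---------------------------------------------------------------------------
# tree-based estimators


def dgcart_total(
    sample: SurveySample,
    class_labels_nonsampled: Sequence[int],
    predictions_nonsampled: Sequence[float],
    h: int,
) -> DomainEstimate:
    """Direct tree-based total: sampled stratum sum plus classified predictions.

    ``mean_hat`` divides by the estimator's own implied stratum size
    ``n_h + r_hat_h`` (sampled members plus non-sampled units classified
    into h); ``lambda_hat`` is the population share of that implied size.
    """
    labels = np.asarray(class_labels_nonsampled)
    preds = np.asarray(predictions_nonsampled, dtype=float)
    r = len(sample.nonsampled_ids)
    if len(labels) != r or len(preds) != r:
        raise ValueError(
            f"classification labels and predictions must cover all {r} "
            f"non-sampled units, got {len(labels)} and {len(preds)}"
        )
    in_h = labels == h
    n_h = sample.n_h(h)
    r_h = int(in_h.sum())
    total = float(sample.y[sample.stratum == h].sum()) + float(preds[in_h].sum())
    size = n_h + r_h
    return DomainEstimate(
        stratum=h,
        total_hat=total,
        mean_hat=total / size if size else 0.0,
        lambda_hat=size / sample.N,
        variant="dgcart_direct",
    )


def _trees_of(model: FittedTree | TreeEnsemble) -> list[FittedTree]:
    if isinstance(model, TreeEnsemble):
        if model.n_trees == 0:
            raise ValueError("empty ensemble")
        return model.trees
    return [model]


def _leaf_lut(tree: FittedTree, attr: str) -> np.ndarray:
    lut = np.full(len(tree.nodes), np.nan)
    for nd in tree.nodes:
        if nd.is_leaf:
            lut[nd.id] = getattr(nd, attr)
    return lut


class _DomainContext:
    """Shared per-sample computations: leaves, labels and predictions.

    Applies every tree to the covariates exactly once so that the direct
    and smoothed variants for all strata reuse the same leaf assignments.
    """

    def __init__(
        self,
        sample: SurveySample,
        class_model: FittedTree | TreeEnsemble,
        reg_model: FittedTree | TreeEnsemble,
    ) -> None:
        self.sample = sample
        X_ns = sample.nonsampled_covariates
        cls_trees = _trees_of(class_model)
        votes = np.stack(
            [_leaf_lut(t, "label")[t.apply(X_ns)] for t in cls_trees]
        ).astype(int)
        classes = np.unique(votes)
        counts = np.stack([(votes == c).sum(axis=0) for c in classes])
        self.labels_ns = classes[np.argmax(counts, axis=0)]

        reg_trees = _trees_of(reg_model)
        self.reg_leaves_s = [t.apply(sample.covariates) for t in reg_trees]
        self.reg_leaves_ns = [t.apply(X_ns) for t in reg_trees]
        self.preds_ns = np.mean(
            [
                _leaf_lut(t, "mean")[lns]
                for t, lns in zip(reg_trees, self.reg_leaves_ns)
            ],
            axis=0,
        )

    def conditional_predictions(self, h: int) -> np.ndarray:
        """Stratum-h conditional leaf mean for every non-sampled unit.

        Per tree, a unit's value is the mean of the sampled stratum-h
        outcomes routed to its leaf, falling back to the overall sampled
        stratum-h mean when the leaf holds none (and to the leaf's overall
        sampled mean when the stratum is unobserved); ensembles average
        over trees.
        """
        y_s = self.sample.y
        member = self.sample.stratum == h
        ybar_sh = float(y_s[member].mean()) if member.any() else None
        out = np.zeros(len(self.sample.nonsampled_ids))
        for ls, lns in zip(self.reg_leaves_s, self.reg_leaves_ns):
            cond = np.empty(len(lns))
            for leaf in np.unique(lns):
                sel = ls == leaf
                if (sel & member).any():
                    m = float(y_s[sel & member].mean())
                elif ybar_sh is not None:
                    m = ybar_sh
                else:
                    m = float(y_s[sel].mean())
                cond[lns == leaf] = m
            out += cond
        return out / len(self.reg_leaves_s)

    def combined(self, h: int) -> DomainEstimate:
        """Classified-size estimator: sampled stratum total plus the
        classified non-sampled count times the combined stratum mean.

        Misclassification perturbs only the implied stratum size here —
        wrong-stratum outcome values never enter, because every classified
        unit contributes the stratum-conditional leaf mean.
        """
        sample = self.sample
        in_h = self.labels_ns == h
        r_h = int(in_h.sum())
        n_h = sample.n_h(h)
        samp = float(sample.y[sample.stratum == h].sum())
        if r_h and n_h:
            ystar = float(self.conditional_predictions(h)[in_h].mean())
        else:
            ystar = 0.0
        total = samp + r_h * ystar
        size = n_h + r_h
        return DomainEstimate(
            stratum=h,
            total_hat=total,
            mean_hat=total / size if size else 0.0,
            lambda_hat=size / sample.N,
            variant="dgcart_combined",
        )

    def smoothed(self, h: int) -> DomainEstimate:
        sample = self.sample
        n, N = sample.n, sample.N
        ybar_sh, n_h = _stratum_sample_mean(sample, h)
        lam = n_h / n
        in_h = self.labels_ns == h
        if in_h.any() and n_h > 0:
            ystar = float(self.conditional_predictions(h)[in_h].mean())
        else:
            ystar = ybar_sh  # uninformative classification: fall back
        total = n * lam * (ybar_sh - ystar) + lam * N * ystar
        return DomainEstimate(
            stratum=h,
            total_hat=total,
            mean_hat=total / (lam * N) if lam > 0 else 0.0,
            lambda_hat=lam,
            variant="dgcart_smoothed",
        )


def dgcart_total_combined(
    sample: SurveySample,
    class_model: FittedTree | TreeEnsemble,
    reg_model: FittedTree | TreeEnsemble,
    h: int,
) -> DomainEstimate:
    """Tree-based total with classified stratum size and combined mean:
    ``sum_s a_hi y_i + r_hat_h * ybar*_h`` where r_hat_h counts non-sampled
    units classified into h and ybar*_h is their combined (stratum-
    conditional) mean.  The reported lambda_hat is the classified share
    ``(n_h + r_hat_h) / N``, which varies with the fitted model."""
    if len(sample.nonsampled_ids) == 0:
        ybar_sh, n_h = _stratum_sample_mean(sample, h)
        return DomainEstimate(
            stratum=h,
            total_hat=n_h * ybar_sh,
            mean_hat=ybar_sh,
            lambda_hat=n_h / sample.N,
            variant="dgcart_combined",
        )
    return _DomainContext(sample, class_model, reg_model).combined(h)


def dgcart_total_smoothed(
    sample: SurveySample,
    class_model: FittedTree | TreeEnsemble,
    reg_model: FittedTree | TreeEnsemble,
    h: int,
) -> DomainEstimate:
    """Smoothed tree-based total, r_hat_h = lambda_hat_h (N - n) weighting.

    ``n lambda_hat_h (ybar_sh - ybar*_h) + lambda_hat_h N ybar*_h`` with
    ybar*_h the combined stratum mean of classified non-sampled units;
    reduces exactly to the expansion estimator when ybar*_h = ybar_sh
    (single-leaf trees, or no unit classified into h).
    """
    if len(sample.nonsampled_ids) == 0:
        ybar_sh, n_h = _stratum_sample_mean(sample, h)
        lam = n_h / sample.n
        return DomainEstimate(
            stratum=h,
            total_hat=lam * sample.N * ybar_sh,
            mean_hat=ybar_sh,
            lambda_hat=lam,
            variant="dgcart_smoothed",
        )
    return _DomainContext(sample, class_model, reg_model).smoothed(h)


def estimate_domains(
    sample: SurveySample,
    class_model: FittedTree | TreeEnsemble | None,
    reg_model: FittedTree | TreeEnsemble | None,
    strata: Sequence[int] | None = None,
    variants: Sequence[str] = VARIANTS,
) -> list[DomainEstimate]:
    """All requested estimator variants for every stratum.

    Tree application to the non-sampled units happens once and is shared
    across strata and variants.
    """
    if strata is None:
        strata = range(1, sample.H + 1)
    unknown = set(variants) - set(VARIANTS)
    if unknown:
        raise ValueError(f"unknown estimator variants: {sorted(unknown)}")
    need_tree = {"dgcart_direct", "dgcart_combined", "dgcart_smoothed"} & set(variants)
    ctx = None
    if need_tree and len(sample.nonsampled_ids):
        if class_model is None or reg_model is None:
            raise ValueError("tree-based variants need fitted class/reg models")
        ctx = _DomainContext(sample, class_model, reg_model)
    out: list[DomainEstimate] = []
    for h in strata:
        if "expansion" in variants:
            out.append(expansion_total(sample, h))
        if "dgcart_direct" in variants:
            if ctx is None:
                out.append(
                    dgcart_total(sample, np.empty(0, dtype=int), np.empty(0), h)
                )
            else:
                out.append(dgcart_total(sample, ctx.labels_ns, ctx.preds_ns, h))
        if "dgcart_combined" in variants:
            if ctx is None:
                out.append(dgcart_total_combined(sample, class_model, reg_model, h))
            else:
                out.append(ctx.combined(h))
        if "dgcart_smoothed" in variants:
            if ctx is None:
                out.append(dgcart_total_smoothed(sample, class_model, reg_model, h))
            else:
                out.append(ctx.smoothed(h))
    return out


# ---------------------------------------------------------------------------
# diagnostics


def conditional_bias(
    moments: ModelMoments,
    leaf_means: Sequence[float],
    lambda_star: float,
    N: int,
    n: int,
) -> float:
    """Model bias of the tree-based total given the classification partition:
    ``(N - n) (lambda*_h sum_l mu_lh - mu_h lambda_h)``."""
    return (N - n) * (
        lambda_star * float(np.sum(leaf_means)) - moments.mu_h * moments.lambda_h
    )


def prediction_error_variance(
    moments: ModelMoments,
    sigma_star_t_sq: float,
    mu_lh: float,
    lambda_star: float,
    N: int,
    n: int,
) -> float:
    """Prediction-error variance of the tree-based total (diagnostic):
    ``(N-n)[{lambda* sigma*_t^2 + mu_lh lambda*(1-lambda*)} +
    {lambda sigma^2 + lambda(1-lambda) mu^2}]``."""
    tree_part = lambda_star * sigma_star_t_sq + mu_lh * lambda_star * (1.0 - lambda_star)
    pop_part = (
        moments.lambda_h * moments.sigma2_h
        + moments.lambda_h * (1.0 - moments.lambda_h) * moments.mu_h**2
    )
    return (N - n) * (tree_part + pop_part)
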