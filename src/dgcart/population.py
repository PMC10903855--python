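"""Finite populations, synthetic generation, and simple random sampling.

The data model mirrors the post-stratification setting: a finite population
``U = {1..N}`` is partitioned into ``H`` mutually exclusive strata, but the
stratum membership indicator ``a_hi`` and the study variable ``y_i`` are
observed only on a sample drawn without replacement.  The superpopulation
model assumed throughout is

    y_i = mu_h + eps_hi,        A_hi ~ Bernoulli(lambda_h),

with independent within-stratum noise ``eps_hi`` of variance ``sigma_h^2``.
The synthetic generator realises this model, optionally adding a logistic
covariate->membership link and a within-stratum covariate signal on the
outcome so that trees have genuine structure to learn, plus pure-noise
covariates as distractors.

Randomness discipline: every public entry point takes a single integer seed
and derives an independent child stream from it via ``SeedSequence([seed,
STREAM_*])``.  Stream ids: 0 = population generation, 1 = SRSWOR draws,
2 = forest resampling (used by :mod:`dgcart.forest`), 3 = generator
coefficient matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

STREAM_GENERATE = 0
STREAM_SAMPLE = 1
STREAM_FOREST = 2

_PROB_TOL = 1e-8


class ConfigurationError(ValueError):
    """Raised when a synthetic-population or run configuration is invalid."""


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic superpopulation.

    Defaults describe a strong-signal two-stratum population: membership is
    driven by a logistic link on the first ``n_informative`` covariates
    (logit scale ``membership_strength``), the outcome carries the stratum
    mean plus a within-stratum covariate signal of slope ``y_signal`` on the
    same informative covariates, and the remaining ``p - n_informative``
    covariates are pure noise.  With ``y_signal=1`` and ``sigma=1`` the
    within-stratum standard deviation of y is ~sqrt(2); the default stratum
    means are ~3 such SDs apart.

    ``membership_probs`` switches to the plain Bernoulli-membership model
    with fixed stratum weights lambda_h (covariates then carry no membership
    information), which is the form used for moment checks of the model.

    ``outcome="count"`` produces a 1-plus-Poisson outcome truncated to
    ``[1, count_max]``, mimicking bounded small-count health outcomes such
    as the number of pregnancy losses (range 1..20).
    """

    N: int = 600
    H: int = 2
    p: int = 8
    n_informative: int = 3
    membership_probs: tuple[float, ...] | None = None
    membership_strength: float = 3.0
    mu: tuple[float, ...] = (2.0, 7.0)
    sigma: tuple[float, ...] = (1.0, 1.0)
    y_signal: float = 1.0
    outcome: str = "normal"
    count_max: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ConfigurationError(f"N must be >= 2, got {self.N}")
        if self.H < 2:
            raise ConfigurationError(f"H must be >= 2, got {self.H}")
        if self.p < 0:
            raise ConfigurationError(f"p must be >= 0, got {self.p}")
        if not 0 <= self.n_informative <= self.p:
            raise ConfigurationError(
                f"n_informative must lie in [0, p={self.p}], got {self.n_informative}"
            )
        if len(self.mu) != self.H or len(self.sigma) != self.H:
            raise ConfigurationError(
                f"mu and sigma must each have H={self.H} entries, "
                f"got {len(self.mu)} and {len(self.sigma)}"
            )
        if any(s <= 0 for s in self.sigma):
            raise ConfigurationError(f"all sigma_h must be > 0, got {self.sigma}")
        if self.membership_probs is not None:
            probs = np.asarray(self.membership_probs, dtype=float)
            if len(probs) != self.H:
                raise ConfigurationError(
                    f"membership_probs must have H={self.H} entries, got {len(probs)}"
                )
            if np.any(probs < 0) or abs(probs.sum() - 1.0) > _PROB_TOL:
                raise ConfigurationError(
                    f"membership_probs must be non-negative and sum to 1, got {tuple(probs)}"
                )
        if self.outcome not in ("normal", "count"):
            raise ConfigurationError(
                f"outcome must be 'normal' or 'count', got {self.outcome!r}"
            )

    @classmethod
    def survey_like(cls, seed: int = 0, **overrides) -> "SyntheticConfig":
        """A weak-separation health-survey-like population.

        Emulates the regime typical of bounded small-count health outcomes
        in two behavioural strata: stratum means a small fraction of the
        within-stratum spread apart, a 1-plus-Poisson count outcome
        truncated to [1, 20], and covariates informative for membership and
        outcome alike.  This is the regime in which post-stratified
        tree-based estimation is designed to pay off: misclassifying a unit
        costs little in outcome contamination, while classification of the
        N - n non-sampled units still sharpens the stratum shares.
        """
        params = dict(mu=(2.0, 2.3), sigma=(1.0, 1.0), outcome="count", seed=seed)
        params.update(overrides)
        return cls(**params)


@dataclass
class Population:
    """A finite population with latent stratum labels.

    ``stratum`` is the evaluation oracle: estimator code must never read it
    (estimators only ever see a :class:`SurveySample`, which carries labels
    for sampled units alone).
    """

    unit_id: np.ndarray
    y: np.ndarray
    stratum: np.ndarray
    covariates: pd.DataFrame
    H: int

    def __post_init__(self) -> None:
        self.unit_id = np.asarray(self.unit_id)
        self.y = np.asarray(self.y, dtype=float)
        self.stratum = np.asarray(self.stratum)
        n = len(self.unit_id)
        if not (len(self.y) == len(self.stratum) == len(self.covariates) == n):
            raise ValueError("unit_id, y, stratum and covariates must have equal length")
        if n < 2:
            raise ValueError(f"population must contain at least 2 units, got {n}")

    @property
    def N(self) -> int:
        return len(self.unit_id)

    @property
    def p(self) -> int:
        return self.covariates.shape[1]


@dataclass
class SurveySample:
    """An SRSWOR sample: outcomes and memberships for sampled units only.

    Non-sampled units contribute covariates alone; their latent labels stay
    behind the population oracle and are structurally absent here.
    """

    sampled_ids: np.ndarray
    y: np.ndarray
    stratum: np.ndarray
    covariates: pd.DataFrame
    nonsampled_ids: np.ndarray
    nonsampled_covariates: pd.DataFrame
    N: int
    H: int

    def __post_init__(self) -> None:
        if len(set(self.sampled_ids.tolist()) & set(self.nonsampled_ids.tolist())):
            raise ValueError("sampled and non-sampled id sets overlap")
        if len(self.sampled_ids) + len(self.nonsampled_ids) != self.N:
            raise ValueError("sampled and non-sampled parts must partition the population")

    @property
    def n(self) -> int:
        return len(self.sampled_ids)

    def n_h(self, h: int) -> int:
        """Number of sampled units observed in stratum h."""
        return int(np.sum(self.stratum == h))

    def lambda_hat(self, h: int) -> float:
        """Sample share of stratum h, lambda_hat_h = n_h / n."""
        return self.n_h(h) / self.n


def _membership_coefs(config: SyntheticConfig) -> np.ndarray:
    """Per-stratum logit coefficient matrix (n_informative x H).

    Columns are fixed unit-norm cosine-basis directions (orthogonal whenever
    H <= n_informative) scaled by ``membership_strength``, so the strength
    parameter directly controls between-stratum separability: for H = 2 the
    logit of stratum-2 membership has slope ``strength * sqrt(2)`` along a
    standard-normal projection of the informative covariates.
    """
    k, H = config.n_informative, config.H
    j = np.arange(k).reshape(-1, 1) + 0.5
    h = np.arange(H).reshape(1, -1)
    M = np.cos(np.pi * j * h / k)
    M /= np.linalg.norm(M, axis=0, keepdims=True)
    return config.membership_strength * M


def generate_population(config: SyntheticConfig) -> Population:
    """Draw one finite population from the synthetic superpopulation.

    Membership: fixed multinomial weights when ``membership_probs`` is set,
    otherwise a multinomial-logit link on the informative covariates.
    Outcome: ``y_i = mu_h + y_signal * z_i + eps_hi`` with
    ``z_i = mean of the informative covariates (scaled to unit variance)``
    and Gaussian noise, or the truncated 1+Poisson count transform of that
    latent value in count mode.  Byte-identical for identical configs.
    """
    rng = _rng(config.seed, STREAM_GENERATE)
    N, H, p, k = config.N, config.H, config.p, config.n_informative

    X = rng.standard_normal((N, p))
    covariates = pd.DataFrame(X, columns=[f"x{j + 1}" for j in range(p)])

    if config.membership_probs is not None:
        probs = np.asarray(config.membership_probs, dtype=float)
        probs = probs / probs.sum()
        stratum = rng.choice(np.arange(1, H + 1), size=N, p=probs)
    else:
        if k == 0:
            raise ConfigurationError(
                "logistic membership needs n_informative >= 1 "
                "(or set membership_probs for label-only membership)"
            )
        scores = X[:, :k] @ _membership_coefs(config)
        scores -= scores.max(axis=1, keepdims=True)
        pr = np.exp(scores)
        pr /= pr.sum(axis=1, keepdims=True)
        u = rng.random((N, 1))
        stratum = 1 + (pr.cumsum(axis=1) < u).sum(axis=1)

    mu = np.asarray(config.mu, dtype=float)[stratum - 1]
    sig = np.asarray(config.sigma, dtype=float)[stratum - 1]
    z = X[:, :k].sum(axis=1) / math.sqrt(k) if k else np.zeros(N)
    latent = mu + config.y_signal * z + rng.normal(0.0, sig)
    if config.outcome == "count":
        rate = np.maximum(latent - 1.0, 0.05)
        y = 1.0 + rng.poisson(rate)
        y = np.minimum(y, float(config.count_max))
    else:
        y = latent

    return Population(
        unit_id=np.arange(1, N + 1),
        y=y,
        stratum=stratum.astype(int),
        covariates=covariates,
        H=H,
    )


def draw_srswor(pop: Population, n: int, seed: int | np.random.Generator) -> SurveySample:
    """Draw a simple random sample of size n without replacement.

    Stratum labels and outcomes are exposed only for the n sampled units;
    the remaining N-n units keep their covariates for classification and
    prediction.  ``seed`` may be an integer (a child stream is derived) or
    an existing Generator (consumed in place, for replicate loops).
    """
    N = pop.N
    if not 1 <= n <= N:
        raise ValueError(f"sample size n must satisfy 1 <= n <= N={N}, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else _rng(seed, STREAM_SAMPLE)
    pos = np.sort(rng.choice(N, size=n, replace=False))
    mask = np.zeros(N, dtype=bool)
    mask[pos] = True
    return SurveySample(
        sampled_ids=pop.unit_id[mask],
        y=pop.y[mask],
        stratum=pop.stratum[mask],
        covariates=pop.covariates.iloc[mask].reset_index(drop=True),
        nonsampled_ids=pop.unit_id[~mask],
        nonsampled_covariates=pop.covariates.iloc[~mask].reset_index(drop=True),
        N=N,
        H=pop.H,
    )


def true_domain_summaries(pop: Population) -> pd.DataFrame:
    """Exact per-stratum size N_h, total T_yh and mean (evaluation oracle).

    Includes every stratum 1..H, with zero rows for empty strata.
    """
    rows = []
    for h in range(1, pop.H + 1):
        sel = pop.stratum == h
        N_h = int(sel.sum())
        total = float(pop.y[sel].sum())
        rows.append(
            {
                "stratum": h,
                "N_h": N_h,
                "total": total,
                "mean": total / N_h if N_h else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("stratum")
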