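# Methods

## Setting and model

A finite population `U = {1, …, N}` is partitioned into `H` mutually
exclusive strata (domains). The goal is the stratum-specific total
`T_yh = Σ_{i∈h} y_i` (and mean `T_yh / N_h`), but membership is observed
only on an SRSWOR sample `s` of size `n`: sampled units reveal the outcome
`y_i` and the indicator `a_hi`; the remaining `N − n` units reveal only
their covariates. The working superpopulation model is

    y_i = μ_h + ε_hi,      A_hi ~ Bernoulli(λ_h),   Var(ε_hi) = σ_h²,

under which the product `A_h Y` has mean `λ_h μ_h` and variance
`σ*_h² = λ_h σ_h² + λ_h (1 − λ_h) μ_h²`.

### Estimators

* **Expansion (baseline)** — `t̂_yhE = (N/n) Σ_s a_hi y_i = N λ̂_h ȳ_h`
  with `λ̂_h = n_h/n`. Model-unbiased, with prediction-error variance
  `N (N − n) σ*_h² / n`. It uses no covariates; all its stratum-size
  information comes from the binomial `λ̂_h`.
* **Direct tree-based** — classify every non-sampled unit with the
  classification tree (`â_hi`), predict its outcome with the regression
  tree (leaf mean `ŷ_i`), and set
  `T̂_tbh = Σ_s a_hi y_i + Σ_{s̄} â_hi ŷ_i`.
  Its reported mean divides by the implied size `n_h + r̂_h`.
* **Combined tree-based** — same classified size `r̂_h`, but each
  classified unit contributes the *combined stratum mean* `ȳ*_h`: the
  average, over units classified into `h`, of the stratum-h conditional
  leaf mean (the mean of sampled stratum-h outcomes routed to that
  regression leaf). Misclassification then perturbs only the stratum
  size, never the outcome values entering the stratum.
* **Smoothed tree-based** — replaces the classified count by its
  expectation under the sample share, `r̂_h = λ̂_h (N − n)`, giving
  `T̂ = n λ̂_h (ȳ_sh − ȳ*_h) + λ̂_h N ȳ*_h`. When classification does not
  divide the data meaningfully (in particular with single-leaf trees)
  `ȳ*_h = ȳ_sh` and the estimator collapses *exactly* to the expansion
  estimator — an identity the test suite asserts to machine precision.

The conditional-bias and prediction-error-variance diagnostics
(`(N−n)(λ* Σ_l μ_lh − μ_h λ_h)` and
`(N−n)[{λ* σ*_t² + μ_lh λ*(1−λ*)} + {λ σ_h² + λ(1−λ) μ_h²}]`) are
reporting-only and never feed back into estimation.

## Trees

Both trees are grown greedily from scratch on the full covariate set:
Gini impurity with majority-vote leaf labels for membership, within-node
variance with leaf means for the outcome. Node gates: `min_split`
(smallest node that may be split), `min_bucket` (smallest admissible
child), `max_depth`, and an rpart-style `cp` (a split must lower the
tree's total impurity by at least `cp ×` root impurity). `delta_o`
implements the variance-reduction stopping rule: splitting continues only
while the largest per-stratum (regression: overall) reduction in pooled
variance across the tree partition stays at or above `delta_o`; the
default 0 leaves stopping to the other gates, since no published value of
the threshold exists. Classification splits are additionally rejected
when either child would hold fewer than two observations of its own
majority stratum, so every leaf label rests on at least two sampled
units; the guard applies to the majority stratum only, because demanding
it of all strata would forbid pure leaves.

Determinism: numeric cuts at midpoints of consecutive distinct sorted
values; equal-gain ties resolve to the lowest covariate index, then the
lowest threshold. Categorical covariates use the classical CART
reduction (categories ordered by outcome mean or majority-stratum share,
then scanned as ordered); a level unseen at prediction time follows the
child with more training rows. Refitting identical data yields an
identical tree.

Forests bag `n_trees` trees on bootstrap resamples (with replacement, at
the sample size) with `mtry` covariates per split (`⌊√p⌋` classification,
`⌊p/3⌋` regression by default). Tree `t` of a forest seeded `s` draws its
randomness from `SeedSequence([s, 2, t])`; classification aggregates by
plurality vote (ties to the lowest stratum), regression by the mean.

### Model grid

The packaged six-model grid (`table2_models()`) pairs five single-tree
configurations with one 500-tree forest. Three printed entries are not
usable as written and are resolved to their evident intent: a fractional
`min_bucket` of 0.67 becomes 1, a zero-padded `cp` of "001" becomes
0.001, and a `min_split` below `min_bucket` (models 3 and 5,
classification) is raised to `min_bucket`.

## Synthetic populations

`SyntheticConfig` realises the superpopulation model with covariates that
carry genuine signal plus distractors:

* `p` standard-normal covariates, the first `n_informative` (default 3 of
  8) informative, the rest pure noise;
* membership either fixed multinomial weights `λ_h` (the pure
  Bernoulli-membership model used in the moment checks) or a
  multinomial-logit link on the informative covariates with deterministic
  unit-norm cosine-basis stratum directions scaled by
  `membership_strength` (default 3; for H = 2 this yields a logistic
  boundary of slope `3√2` along a standard-normal projection, Bayes
  misclassification ≈ 0.13);
* outcome `y_i = μ_h + y_signal · z_i + ε_hi` with `z_i` the scaled mean
  of the informative covariates (so covariates inform the outcome within
  strata too), or a `1 + Poisson` transform truncated to `[1, 20]` in
  count mode, mimicking bounded small-count health outcomes.

Defaults (`N = 600`, `H = 2`, `μ = (2, 7)`, `σ = (1, 1)`,
`y_signal = 1`) give conditional stratum means about three within-stratum
standard deviations apart — a *wide-separation* population.
`SyntheticConfig.survey_like()` instead emulates the weak-separation
regime typical of health-survey count outcomes (`μ = (2, 2.3)`, count
mode): realised stratum means differ by well under one within-stratum SD.

All randomness flows from one root seed through documented child streams
(0 generation, 1 sampling, 2 forests), so every component is
independently reproducible and study reports are byte-identical across
reruns.

What the generator does *not* emulate: real survey covariates are mixed
categorical/ordinal with complex dependence, strata are rarely a clean
logistic function of three covariates, and outcomes are not exactly
1+Poisson. Passing tests therefore certify the estimators' algebra,
determinism and qualitative behaviour under the stated model — not
performance guarantees on any particular survey.

## Bootstrap study and metrics

`run_bootstrap_study` holds the population fixed, draws Q independent
SRSWOR replicates per sample size, fits every model of the grid, forms
all estimator variants, and aggregates

    EAPE = (1/Q) Σ_j |est_j − truth|,   MSPE = (1/Q) Σ_j (est_j − truth)²,
    RE   = MSPE(expansion) / MSPE(model).

Metrics are computed on the stratum-mean scale by default (estimate =
total / implied stratum size against the true stratum mean), which keeps
EAPE magnitudes comparable across strata; a `scale: total` switch uses
raw totals. Replicates in which a stratum draws no sampled member are
excluded from that stratum's cells for *all* models alike (count
reported), keeping RE a fair ratio. The per-replicate estimate log is
always retained so every summary can be recomputed or resumed.

## Separation regimes (a finding of this package's own study)

The bootstrap study exhibits two sharply different regimes:

* **Weak separation** (survey-like populations, stratum means ≲ 0.5 SD
  apart): misclassifying a unit costs little outcome contamination while
  classifying all N − n units still sharpens stratum sizes, and the
  regression tree pools information across strata. The tree-based
  estimators beat the expansion baseline (RE > 1) for most grids, and the
  bagged forest is consistently the most efficient model — the pattern
  the method was designed around.
* **Wide separation** (means ~3 SD apart): any small-sample axis-aligned
  classifier retains ≳10–25% spatially persistent misclassification on a
  genuinely multi-covariate membership boundary, and with strata this far
  apart the induced contamination or size bias exceeds the expansion
  estimator's binomial λ̂ noise. The direct estimator then falls well
  below RE = 1, and even the contamination-free combined/smoothed
  variants only reach parity unless classification is near-perfect.
  The acceptance test `test_strong_signal_study_gives_re_above_one_for_
  every_model` asserts the uniform-RE pattern under this regime and is
  expected to fail; it is kept as an executable record of the boundary
  of the method's usefulness.

Problem sizes in the tests and acceptance script (Q = 500–1000 replicate
studies at n = 50, a 100-tree forest in the study grid, 20,000-replicate
moment checks) were chosen as the smallest sizes at which the Monte-Carlo
error is clearly below the effects being measured.

## Known limitations

* No pruning by cross-validation, surrogate splits, multiway splits, or
  missing-value handling; rows with missing values must be dropped
  upstream.
* No design-based variance estimators or confidence intervals; the model
  variance formula applies to the expansion estimator only.
* The stopping threshold `delta_o` is applied to the largest per-stratum
  variance reduction when H > 2; the source formulation is per-stratum
  and silent on how strata share one tree.
* Out-of-bag variance estimation for the forest-based total is not
  implemented.
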