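import numpy as np
import pandas as pd
import pytest

import dgcart as dg
from dgcart.evaluation import (
    StudyConfig,
    run_replicates,
    summarize_replicates,
    table2_models,
)
from dgcart.population import generate_population, true_domain_summaries


@pytest.fixture(scope="session")
def strong_population():
    """The default strong-signal synthetic population (fixed seed)."""
    return generate_population(dg.SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def survey_study_report():
    """Bootstrap study on the weak-separation survey-like population.

    One shared Q=500 run of the full model grid (forest scaled to 60 trees)
    at n=50, summarised on the stratum-mean scale with the direct
    estimator; used by the forest-dominance and study-pattern tests.
    """
    pop = generate_population(dg.SyntheticConfig.survey_like(seed=7))
    truth = true_domain_summaries(pop)
    cfg = StudyConfig(
        population=pop,
        sample_sizes=(50,),
        models=tuple(table2_models(rf_trees=60)),
        Q=500,
        seed=5,
        variants=("dgcart_direct",),
    )
    reps = run_replicates(cfg, pop)
    return summarize_replicates(reps, truth, "mean")


def make_sample(
    y, stratum, N, H=2, covariates=None, nonsampled_covariates=None
) -> dg.SurveySample:
    """Hand-build a SurveySample; covariates default to empty frames."""
    y = np.asarray(y, dtype=float)
    stratum = np.asarray(stratum, dtype=int)
    n = len(y)
    if covariates is None:
        covariates = pd.DataFrame(index=range(n))
    if nonsampled_covariates is None:
        nonsampled_covariates = pd.DataFrame(index=range(N - n))
    return dg.SurveySample(
        sampled_ids=np.arange(1, n + 1),
        y=y,
        stratum=stratum,
        covariates=covariates,
        nonsampled_ids=np.arange(n + 1, N + 1),
        nonsampled_covariates=nonsampled_covariates,
        N=N,
        H=H,
    )
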