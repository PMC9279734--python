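import numpy as np
import pandas as pd
import pytest

from occultln import (
    BetaBinomialParams,
    NodalCohort,
    NodalSimConfig,
    SurvivalSimConfig,
    simulate_nodal_cohort,
    simulate_survival_cohort,
)

#: Point estimates of the latent positivity law used throughout the tests
#: (the fitted values for central-compartment nodes in papillary
#: microcarcinoma: alpha = 2.50, beta = 6.21, true prevalence 0.389).
ALPHA, BETA, PREVALENCE = 2.50, 6.21, 0.389


@pytest.fixture(scope="session")
def params() -> BetaBinomialParams:
    return BetaBinomialParams(ALPHA, BETA)


@pytest.fixture(scope="session")
def positive_cohort() -> NodalCohort:
    """All-truly-positive cohort with uniform yields (clean fitting substrate)."""
    cfg = NodalSimConfig(
        n_patients=4000,
        true_prevalence=1.0,
        alpha=ALPHA,
        beta=BETA,
        yield_distribution="uniform",
        yield_params={"lo": 2, "hi": 15},
        seed=20,
    )
    return simulate_nodal_cohort(cfg)


@pytest.fixture(scope="session")
def mixed_cohort() -> NodalCohort:
    """Cohort at the stated prevalence with the default yield law."""
    return simulate_nodal_cohort(NodalSimConfig(n_patients=20000, seed=21))


@pytest.fixture(scope="session")
def survival_records() -> pd.DataFrame:
    cfg = SurvivalSimConfig(
        n_patients=6000,
        covariate_effects={"age_per_10y": 0.6, "male": 0.3},
        inject_ineligible_fraction=0.04,
        seed=22,
    )
    return simulate_survival_cohort(cfg)


@pytest.fixture()
def toy_nodal_table() -> pd.DataFrame:
    return pd.DataFrame(
        {"nodes_examined": [3, 5, 2, 8, 4], "nodes_positive": [1, 0, 2, 3, 0]}
    )
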