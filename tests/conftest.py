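import pytest

from oxval import (
    CohortSpec,
    OutcomeSpec,
    linear_predictors,
    sample_cohort,
    simulate_outcomes,
)
from oxval import presets


@pytest.fixture(scope="session")
def sweden_coefs():
    return presets.sweden_synthetic_coefficients()


@pytest.fixture(scope="session")
def tajik_coefs():
    return presets.tajik_recalibrated_coefficients()


@pytest.fixture(scope="session")
def tajik_cohort_50k():
    """One 50,000-record Tajik-case-mix cohort shared across recovery tests
    (outcomes are attached per test with their own seeds)."""
    return sample_cohort(CohortSpec(n=50_000, seed=20240101))


@pytest.fixture(scope="session")
def tajik_lp_50k(tajik_cohort_50k, sweden_coefs):
    """Linear predictors of the shared cohort under the original model."""
    return linear_predictors(tajik_cohort_50k, sweden_coefs)


@pytest.fixture(scope="session")
def calibrated_cohort(tajik_cohort_50k, sweden_coefs):
    """Cohort with outcomes drawn from the scoring model's own risks
    (perfectly calibrated by construction); returns (cohort, true risks)."""
    spec = OutcomeSpec(true_model=sweden_coefs, seed=7)
    return simulate_outcomes(tajik_cohort_50k, spec)
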