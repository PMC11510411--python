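import numpy as np
import pytest

from psomipd import (
    CohortConfig,
    DoseEvent,
    PDParams,
    PKIndividual,
    PKPopulation,
    Regimen,
    generate_cohort,
)


@pytest.fixture(scope="session")
def pk_pop() -> PKPopulation:
    return PKPopulation()


@pytest.fixture(scope="session")
def typical_ind(pk_pop) -> PKIndividual:
    from psomipd import apply_covariates

    return apply_covariates(pk_pop, pk_pop.ref_weight_kg)


@pytest.fixture(scope="session")
def final_pd() -> PDParams:
    """PD parameters at the final-model point estimates and the mean baseline."""
    return PDParams(kout=0.016, imax=0.97, ic50=0.07, pasi0=14.4)


@pytest.fixture(scope="session")
def single_dose() -> list[DoseEvent]:
    return [DoseEvent(0.0, 90.0)]


@pytest.fixture(scope="session")
def q12w() -> Regimen:
    return Regimen(90.0, 12.0, n_cycles=5)


@pytest.fixture(scope="session")
def small_cohort():
    """Six sparse synthetic patients, shared across estimation tests."""
    return generate_cohort(CohortConfig(n_patients=6), seed=202)


@pytest.fixture(scope="session")
def rich_cohort():
    """Twelve patients with biweekly PASI sampling for recovery-style checks."""
    return generate_cohort(
        CohortConfig(n_patients=12, rich_pd_sampling=True), seed=77
    )
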