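import numpy as np
import pytest

from cisdose import (
    CISPLATIN_POPULATION,
    DosingEvent,
    PriorModel,
    SynthConfig,
    generate_cohort,
)


@pytest.fixture(scope="session")
def population():
    return CISPLATIN_POPULATION


@pytest.fixture(scope="session")
def prior():
    return PriorModel(population=CISPLATIN_POPULATION)


@pytest.fixture(scope="session")
def three_course_regimen():
    """Three 164 mg / 3 h infusions every 21 days."""
    return [DosingEvent(164.0, 0.0), DosingEvent(164.0, 504.0),
            DosingEvent(164.0, 1008.0)]


@pytest.fixture(scope="session")
def small_cohort():
    """A 20-patient synthetic cohort shared across tests."""
    return generate_cohort(SynthConfig(n_patients=20, seed=42))


def random_macros(rng):
    """A random valid macro parameter set near the population values."""
    pop = CISPLATIN_POPULATION
    for _ in range(100):
        coeffs = np.array([pop.A, pop.B, pop.C]) * np.exp(rng.normal(0, 0.3, 3))
        rates = np.array([pop.alpha, pop.beta, pop.gamma]) * np.exp(
            rng.normal(0, 0.2, 3))
        rates = np.sort(rates)[::-1]
        if rates[0] > rates[1] * 1.05 and rates[1] > rates[2] * 1.05:
            from cisdose import PopulationPK
            return PopulationPK(*coeffs, *rates)
    raise RuntimeError("could not draw separated rates")
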