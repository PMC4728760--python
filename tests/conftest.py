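import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dynmix as dm

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def base_params() -> dm.SimulationParams:
    return dm.SimulationParams()


@pytest.fixture(scope="session")
def small_params() -> dm.SimulationParams:
    """A fast, miniature world for engine tests: 30 clinics of median size
    12, so the full dynamic loop runs in well under a second."""
    return dm.SimulationParams(
        n_clinics=30, mu_N=math.log(12.0), theta=20, seed=424242
    )


@pytest.fixture(scope="session")
def small_population(small_params) -> dm.Population:
    return dm.generate_population(small_params, seed=424242)


@pytest.fixture(scope="session")
def small_training_ids(small_population):
    return dm.select_training_clinics(small_population, np.random.default_rng(7))


@pytest.fixture(scope="session")
def base_population(base_params) -> dm.Population:
    """One full-scale population (~40k patients), shared across tests."""
    return dm.generate_population(base_params, seed=20160127)


@pytest.fixture(scope="session")
def base_training(base_population):
    ids = dm.select_training_clinics(base_population, np.random.default_rng(3))
    return ids, base_population.patients_of(ids)
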