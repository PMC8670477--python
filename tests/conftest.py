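import numpy as np
import pytest

from mbmodel.network import ModelSpec, ParamDistributions, calibrate, sample_population
from mbmodel.odors import NoiseModel, generate_base_panel, make_trials


@pytest.fixture(scope="session")
def small_panel():
    """24-PN, 20-odor panel used across unit tests."""
    return generate_base_panel(20, 24, rng_seed=101)


@pytest.fixture(scope="session")
def dists():
    return ParamDistributions()


@pytest.fixture(scope="session")
def small_spec():
    """Reduced population size keeps unit tests fast."""
    return ModelSpec(n_kc=400)


@pytest.fixture(scope="session")
def small_random_spec():
    return ModelSpec(
        variable_w=True, variable_N=True, variable_theta=True, n_kc=400
    )


@pytest.fixture(scope="session")
def calibrated_homog(small_panel, small_spec, dists):
    pop = sample_population(small_spec, dists, n_pn=24, rng_seed=7)
    return calibrate(pop, small_panel.rates, small_spec)


@pytest.fixture(scope="session")
def calibrated_random(small_panel, small_random_spec, dists):
    pop = sample_population(small_random_spec, dists, n_pn=24, rng_seed=7)
    return calibrate(pop, small_panel.rates, small_random_spec)


@pytest.fixture(scope="session")
def noisy_trials(small_panel):
    return make_trials(small_panel, NoiseModel(), n_trials=5, rng_seed=42)
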