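import numpy as np
import pytest

from bioemit import (
    IMPACTOR_BINS,
    NoiseModel,
    generate_scenario,
    simulate_observations,
)


@pytest.fixture(scope="session")
def scenario():
    """Default classroom-like ground-truth scenario."""
    return generate_scenario(seed=12345)


@pytest.fixture(scope="session")
def noiseless_obs(scenario):
    """One noise-free realisation: every observable equals its expectation."""
    noise = NoiseModel(concentration_cv=0.0, ct_sd=0.0, read_depth=0, tracer_cv=0.0)
    return simulate_observations(scenario, noise)


@pytest.fixture
def rng():
    return np.random.default_rng(777)


@pytest.fixture(scope="session")
def grid():
    return IMPACTOR_BINS
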