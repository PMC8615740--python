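import numpy as np
import pytest

from mseplsc import MSEParams, SimulationConfig, simulate_cohort
from mseplsc.pipeline import _features_from_dataset


@pytest.fixture(scope="session")
def small_config():
    """A cohort small enough for seconds-scale end-to-end runs."""
    return SimulationConfig(
        group_sizes=(3, 3, 3),
        n_samples=2_000,
        mse_params=MSEParams(tau_max=4),
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    return _features_from_dataset(small_cohort, "valid")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
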