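import numpy as np
import pytest

from teahsi.synthetic_data import (
    SimulationConfig,
    build_spectral_library,
    simulate_dataset,
    simulate_reference_table,
)


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def default_library(default_config):
    return build_spectral_library(default_config.band_count, seed=default_config.seed)


@pytest.fixture(scope="session")
def default_dataset(default_config):
    """The study-scale dataset: 6 days x 15 samples, 508 bands, seed 0."""
    return simulate_dataset(default_config)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Reduced problem for fast unit tests (structure, not study conditions)."""
    return SimulationConfig(
        n_samples_per_day=4, image_shape=(12, 12), band_count=64, seed=7
    )


@pytest.fixture(scope="session")
def small_table(small_config):
    return simulate_reference_table(small_config)


@pytest.fixture(scope="session")
def planted_signal():
    """Regression problem with exactly 5 informative bands among 508.

    Low observation noise so the informative set is recoverable; ground
    truth indices are returned with the data.
    """
    rng = np.random.default_rng(1234)
    n, p = 90, 508
    informative = np.array([50, 150, 250, 350, 450])
    X = rng.standard_normal((n, p))
    beta = np.zeros(p)
    beta[informative] = [1.0, -0.8, 0.6, 0.9, -0.7]
    y = X @ beta + 0.01 * rng.standard_normal(n)
    return X, y, informative
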