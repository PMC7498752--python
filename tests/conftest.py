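"""Shared fixtures: small synthetic datasets sized for fast unit tests."""

import numpy as np
import pytest

from eegmvpa.preprocess import PreprocessParams, preprocess_epochs
from eegmvpa.simulate import SimulationConfig, simulate_epochs


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A compact but structured simulation: 8 conditions, 2 domains."""
    return SimulationConfig(
        n_subjects=3,
        n_channels=12,
        sampling_rate=100.0,
        n_trials_per_condition=10,
        snr=3.0,
        artifact_probability=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def null_config() -> SimulationConfig:
    """Same geometry but with no condition-dependent signal."""
    return SimulationConfig(
        n_subjects=3,
        n_channels=12,
        sampling_rate=100.0,
        n_trials_per_condition=10,
        snr=0.0,
        artifact_probability=0.0,
        seed=13,
    )


@pytest.fixture(scope="session")
def epochs(small_config):
    return simulate_epochs(small_config, 0)


@pytest.fixture(scope="session")
def features(epochs):
    feats, _, _ = preprocess_epochs(epochs, PreprocessParams())
    return feats


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
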