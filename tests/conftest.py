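"""Shared fixtures: small simulated datasets reused across test modules."""

import numpy as np
import pytest

from survcoxbench import SimulationConfig, simulate_dataset
from survcoxbench.cox.penalized import PenalizedConfig


@pytest.fixture(scope="session")
def small_ds():
    """n=200, p=2, m=20, moderate signal — cheap enough for any fit."""
    ds, truth = simulate_dataset(SimulationConfig(
        n=200, p=2, m=20, a_true=0.5, genetic_variance=0.5, censoring=0.2, seed=42))
    return ds, truth


@pytest.fixture(scope="session")
def medium_ds():
    """n=300, p=3, m=200, polygenic signal."""
    ds, truth = simulate_dataset(SimulationConfig(
        n=300, p=3, m=200, a_true=0.5, genetic_variance=1.0, censoring=0.3, seed=7))
    return ds, truth


@pytest.fixture(scope="session")
def null_ds():
    """Expressions carry no survival information."""
    ds, truth = simulate_dataset(SimulationConfig(
        n=250, p=2, m=100, a_true=0.5, genetic_variance=0.0, architecture="null",
        censoring=0.3, seed=13))
    return ds, truth


@pytest.fixture(scope="session")
def fast_penalized_config():
    """Reduced path/tuning workload for harness-level tests."""
    def make(alpha):
        return PenalizedConfig(alpha=alpha, n_lambda=25, n_subsample=5,
                               lambda_min_ratio=0.05)
    return make


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
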