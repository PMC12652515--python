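"""Shared fixtures: small synthetic datasets reused across test modules."""

import numpy as np
import pytest

from beernir.beer_simulator import NoiseModel, simulate_default_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The default 336-sample synthetic study dataset, seed 1."""
    return simulate_default_dataset(seed=1)


@pytest.fixture(scope="session")
def silent_dataset():
    """Noise-free variant of the default dataset (same designs, seed 1)."""
    return simulate_default_dataset(seed=1, noise=NoiseModel.silent())


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def linear_regression_data():
    """Small noiseless linear problem: y depends on 3 of 20 columns."""
    rng = np.random.default_rng(7)
    X = rng.normal(size=(60, 20))
    beta = np.zeros(20)
    beta[[2, 9, 17]] = [1.5, -2.0, 0.8]
    y = X @ beta + 3.0
    return X, y, np.array([2, 9, 17])
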