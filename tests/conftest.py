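import numpy as np
import pytest

from stabsel.synthetic import paperlike_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


@pytest.fixture(scope="session")
def trial_dataset():
    """One study-scale simulated mating experiment (498 pairs)."""
    dataset, config = paperlike_dataset(seed=7)
    return dataset, config


def brute_force_ols(X, y):
    """Normal-equations oracle, independent of the estimation path."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    return np.linalg.solve(X.T @ X, X.T @ y)
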