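import numpy as np
import pytest
from hypothesis import settings

import oxisleep as ox

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study set: 400 apnea + 600 normal minutes,
    generator seed 42."""
    labeled = ox.simulate_labeled_dataset(ox.SimulationConfig(seed=42), 400, 600)
    X, y = ox.build_matrix(labeled)
    return X, y


@pytest.fixture(scope="session")
def small_model(default_dataset):
    """An SVM fitted on the default study set (shared, read-only)."""
    X, y = default_dataset
    return ox.SpO2SVMClassifier().fit(X, y)
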