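import numpy as np
import pandas as pd
import pytest

from gagmced.features import add_derived_features
from gagmced.pipeline import training_matrix
from gagmced.simulate import GeneratorConfig, generate_development_cohort


@pytest.fixture(scope="session")
def dev_cohort():
    """Default development-style synthetic cohort (both fluids, 500 subjects)."""
    return generate_development_cohort(seed=11)


@pytest.fixture(scope="session")
def dev_features(dev_cohort):
    return add_derived_features(dev_cohort.data)


@pytest.fixture(scope="session")
def combined_matrix(dev_cohort):
    """(X, y, feature names, standardizer, wide table) for the combined fluid."""
    return training_matrix(dev_cohort.data, "combined")


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny cohort for fast I/O and CLI tests."""
    cfg = GeneratorConfig(n_healthy=30, n_per_cancer_type=6)
    return generate_development_cohort(cfg, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
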