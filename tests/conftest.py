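import numpy as np
import pandas as pd
import pytest

from progfuse.cohort import CohortConfig, generate_cohort
from progfuse.experiments import prepare_views


@pytest.fixture(scope="session")
def small_cohort():
    """A small default-structure cohort shared across tests."""
    cfg = CohortConfig(
        n_samples=150, n_genes=120, n_informative_genes=25, seed=11
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_views(small_cohort):
    return prepare_views(small_cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_two_class(rng, n=20, p=5, seed=None):
    """Random standardized two-class instance with both classes present."""
    if seed is not None:
        rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    y = np.zeros(n, dtype=int)
    y[: max(2, n // 3)] = 1
    rng.shuffle(y)
    if y.sum() < 2 or y.sum() > n - 2:
        y[:2] = 1
        y[2:] = 0
    return X, y


def continuous_meta(p):
    return pd.DataFrame({"kind": ["continuous"] * p})
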