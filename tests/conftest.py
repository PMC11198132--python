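import numpy as np
import pytest

from combireg import LabelledDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_dataset(rng):
    """Small dense dataset with a real signal: y = X b + noise, c = 0."""
    n, p = 60, 8
    X = rng.standard_normal((n, p))
    beta = np.array([1.5, -1.0, 0.8, 0.0, 0.0, 0.0, 0.0, 0.0])
    y = X @ beta + rng.standard_normal(n)
    return LabelledDataset(X=X, y=y, c=0.0, direction="gt")


@pytest.fixture
def wide_dataset(rng):
    """p > n dataset in the style of the synthetic generator."""
    n, p = 50, 120
    X = rng.standard_normal((n, p))
    beta = np.zeros(p)
    beta[:6] = rng.standard_normal(6) * 1.5
    y = X @ beta + rng.standard_normal(n)
    return LabelledDataset(X=X, y=y, c=0.0, direction="gt")
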