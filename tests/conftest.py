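import numpy as np
import pytest

from poismix.model_core import ComponentParams, CountDataset, WeightModel


def make_dataset(n=40, p=2, q=2, seed=0, y_max=6):
    """Small random dataset with intercepted design blocks."""
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p))])
    W = np.column_stack([np.ones(n), rng.normal(size=(n, q))])
    y = rng.integers(0, y_max + 1, size=n)
    return CountDataset(y, X, W)


def random_params(K=2, p=2, seed=0, scale=0.5):
    rng = np.random.default_rng(seed)
    return ComponentParams(rng.normal(scale=scale, size=K), rng.normal(scale=scale, size=(K, p)))


def random_gate(K=2, q=2, seed=0, scale=0.5):
    rng = np.random.default_rng(seed)
    G = rng.normal(scale=scale, size=(K, 1 + q))
    G[0] = 0.0
    return WeightModel("concomitant", gamma0=G[:, 0], gamma=G[:, 1:])


@pytest.fixture
def small_data():
    return make_dataset(n=40, p=2, q=2, seed=3)
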