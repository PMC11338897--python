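import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_dataset():
    """16 tiny phantom pairs with full ground truth."""
    from sctkit.phantom import make_dataset

    pairs, manifest = make_dataset(16, seed=7)
    return pairs, manifest


def numerical_gradient(f, x, eps=1e-3):
    """Central-difference gradient of a scalar function of an array."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        xp = x.copy()
        xp[i] += eps
        xm = x.copy()
        xm[i] -= eps
        g[i] = (f(xp) - f(xm)) / (2 * eps)
    return g
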