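import numpy as np
import pytest

from octarec import angio, phantom


@pytest.fixture(scope="session")
def small_spec():
    return phantom.PhantomSpec(grid_size=(32, 32, 16), n_vessels=4,
                               radius_range=(1.0, 2.0), seed=7)


@pytest.fixture(scope="session")
def small_series(small_spec):
    return phantom.make_series(small_spec, n_repeats=8)


@pytest.fixture(scope="session")
def small_pairs(small_series):
    return angio.make_pairs(small_series, r=2, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def numerical_gradient(f, x0, eps=1e-6):
    """Central-difference gradient of a scalar function of an array."""
    g = np.zeros_like(x0)
    it = np.nditer(x0, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        xp = x0.copy(); xp[i] += eps
        xm = x0.copy(); xm[i] -= eps
        g[i] = (f(xp) - f(xm)) / (2 * eps)
    return g
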