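import numpy as np
import pytest

from fctransfer import Hyperparams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_hp():
    """Hyperparameters sized for toy networks in unit tests."""
    return Hyperparams(layer_sizes=(3,), lambda_l2=0.001, beta=2.0, rho=0.05,
                       max_epochs=200, seed=0)


def finite_difference_gradient(f, w0, eps=1e-6):
    """Central finite differences of a scalar function, the gradient oracle."""
    w0 = np.asarray(w0, dtype=float)
    g = np.zeros_like(w0)
    for i in range(w0.size):
        wp = w0.copy(); wp[i] += eps
        wm = w0.copy(); wm[i] -= eps
        g[i] = (f(wp) - f(wm)) / (2 * eps)
    return g


def max_relative_error(a, b, floor=1e-8):
    a = np.asarray(a); b = np.asarray(b)
    return float(np.max(np.abs(a - b) / np.maximum(floor, np.abs(a) + np.abs(b))))
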