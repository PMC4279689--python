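import numpy as np
import pytest

from synforest import Dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def reg_data(rng):
    """Small regression dataset with real signal."""
    n, p = 120, 6
    X = rng.random((n, p))
    y = 3.0 * X[:, 0] + np.sin(4 * X[:, 1]) + 0.2 * rng.standard_normal(n)
    return Dataset(X=X, y=y, task="regression")


@pytest.fixture
def noise_reg_data(rng):
    """Regression data whose response is independent of the features."""
    n, p = 120, 6
    return Dataset(
        X=rng.random((n, p)), y=rng.standard_normal(n), task="regression"
    )


@pytest.fixture
def clf_data(rng):
    """Three-class Gaussian blobs."""
    n_per, p, J = 40, 5, 3
    centers = rng.standard_normal((J, p)) * 2.0
    X = np.vstack(
        [centers[j] + rng.standard_normal((n_per, p)) for j in range(J)]
    )
    y = np.repeat(np.arange(J), n_per)
    order = rng.permutation(len(y))
    return Dataset(X=X[order], y=y[order], task="multiclass", J=J)
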