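import numpy as np
import pytest

from ssgic import Dataset, LossSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_logistic_data(n, p, beta, seed, intercept=0.0):
    """Gaussian design with a Bernoulli(logit) response; returns raw Dataset."""
    r = np.random.default_rng(seed)
    X = r.standard_normal((n, p))
    from scipy.special import expit

    prob = expit(intercept + X @ beta)
    y = (r.random(n) < prob).astype(float)
    return Dataset(X, y)


@pytest.fixture
def small_data(rng):
    """A 60 x 6 informative logistic dataset, standardized."""
    beta = np.array([1.5, -1.0, 0.5, 0.0, 0.0, 0.0])
    return make_logistic_data(60, 6, beta, seed=7).standardize()


@pytest.fixture(params=["logistic", "quadratic", "huber"])
def any_loss(request):
    return LossSpec(request.param)
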