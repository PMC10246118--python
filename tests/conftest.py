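import numpy as np
import pytest

from evkf.expfam import (
    BernoulliFamily,
    ContinuousBernoulliFamily,
    GammaFamily,
    GaussianFamily,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_natural(family, rng):
    """A random valid natural-parameter vector for any shipped family."""
    if isinstance(family, GaussianFamily):
        L = family.dim_z
        m = rng.normal(scale=1.0, size=L)
        W = rng.normal(size=(L, L)) / np.sqrt(L)
        P = W @ W.T + 0.3 * np.eye(L)
        return family.from_moments(m, P)
    if isinstance(family, (ContinuousBernoulliFamily, BernoulliFamily)):
        return family.natural(rng.normal(scale=2.0, size=family.dim_z))
    if isinstance(family, GammaFamily):
        alpha = rng.uniform(0.5, 5.0, size=family.dim_z)
        beta = rng.uniform(0.3, 4.0, size=family.dim_z)
        return family.from_shape_rate(alpha, beta)
    raise TypeError(family)


ALL_FAMILIES = [
    GaussianFamily(1),
    GaussianFamily(3),
    ContinuousBernoulliFamily(2),
    GammaFamily(2),
    BernoulliFamily(2),
]


@pytest.fixture(params=ALL_FAMILIES, ids=lambda f: f"{f.name}-L{f.dim_z}")
def family(request):
    return request.param
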