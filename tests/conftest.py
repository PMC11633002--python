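import numpy as np
import pytest
from hypothesis import settings

from splicecor.kernel import build_kernel

settings.register_profile("suite", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def draw_instance(seed, n=60, k=4, n_cov=2, beta1=0.0, sigma_Int2=0.0,
                  sigma_u2=0.3, sigma_e2=1.0, gamma=0.5):
    """A single (y, x, Z, kernel) instance from the generative model."""
    rng = np.random.default_rng(seed)
    ier = rng.dirichlet(np.ones(k), size=n).T
    kernel = build_kernel(ier)
    f = kernel.factor()
    x = rng.standard_normal(n)
    Z = np.column_stack([np.ones(n), rng.standard_normal((n, n_cov))])
    b2 = np.sqrt(sigma_Int2) * (f @ rng.standard_normal(f.shape[1]))
    u = np.sqrt(sigma_u2) * (f @ rng.standard_normal(f.shape[1]))
    y = (x * beta1 + x * b2 + Z @ np.full(Z.shape[1], gamma) + u
         + np.sqrt(sigma_e2) * rng.standard_normal(n))
    return y, x, Z, kernel


@pytest.fixture
def small_instance():
    return draw_instance(seed=11, n=60)
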