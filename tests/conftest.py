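import numpy as np
import pytest

from emborder.acm import ACMParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """Parameters sized for 16x16 oracle instances (small kernel support)."""
    return ACMParams(lambda1=0.8, lambda2=1.1, eta1=0.9, eta2=1.2, nu=0.7,
                     sigma=1.0, kernel_truncation=2.0, epsilon=1.0)


def random_instance(rng, shape=(16, 16)):
    """A random image/level-set pair for oracle comparisons."""
    image = rng.uniform(0.0, 1.0, shape)
    phi = rng.normal(0.0, 1.5, shape)
    return image, phi
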