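import numpy as np
import pytest

from projgauss import GaussianParams


def random_gaussian(n: int, rng: np.random.Generator, scale: float = 1.0) -> GaussianParams:
    """A generic random latent Gaussian for oracle tests."""
    mu = rng.standard_normal(n)
    A = rng.standard_normal((n, n)) * scale
    sigma = A @ A.T + 0.1 * scale * scale * np.eye(n)
    return GaussianParams(mu, sigma)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
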