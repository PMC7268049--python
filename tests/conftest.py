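import numpy as np
import pytest
from scipy.signal import lfilter


def ar2(rng, n, coeffs=(1.3, -0.4), burn=200):
    """AR(2) colored-noise series, the pipeline's standard test signal."""
    a = np.concatenate([[1.0], -np.asarray(coeffs)])
    return lfilter([1.0], a, rng.standard_normal(n + burn))[burn:]


def ar2_pair(rng, n, rho, coeffs=(1.3, -0.4)):
    """Two AR(2) channels with zero-lag correlation rho."""
    L = np.linalg.cholesky(np.array([[1.0, rho], [rho, 1.0]]))
    return L @ np.vstack([ar2(rng, n, coeffs) for _ in range(2)])


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
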