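import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_sparse_system(rng, n=64, m=32, k=3, min_mag=1.0):
    """Noise-free Gaussian system with a k-sparse ground truth."""
    Phi = rng.normal(size=(m, n))
    Phi /= np.linalg.norm(Phi, axis=0)
    x = np.zeros(n)
    idx = rng.choice(n, size=k, replace=False)
    signs = np.where(rng.random(k) < 0.5, -1.0, 1.0)
    x[idx] = signs * rng.uniform(min_mag, min_mag + 1.0, size=k)
    return Phi, x, Phi @ x
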