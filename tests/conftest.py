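import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20190705)


def random_density_matrix(rng, d):
    """Random valid density matrix (positive, unit trace)."""
    a = rng.normal(size=(d, d)) + 1j * rng.normal(size=(d, d))
    rho = a @ a.conj().T
    return rho / np.trace(rho)


def random_hermitian(rng, d, scale=1.0):
    a = rng.normal(size=(d, d)) + 1j * rng.normal(size=(d, d))
    return scale * 0.5 * (a + a.conj().T)
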