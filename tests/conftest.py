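import numpy as np
import pytest

from swdkit.params import NodeParams, load_transfer_coefficients
from swdkit.signals import gamma_basis


@pytest.fixture(scope="session")
def coeffs():
    """Shipped transfer-function coefficients (fitted against the MC oracle)."""
    return load_transfer_coefficients()


@pytest.fixture(scope="session")
def params():
    return NodeParams()


@pytest.fixture(scope="session")
def basis():
    return gamma_basis(TR=2.0)


@pytest.fixture(scope="session")
def small_connectome():
    from swdkit.synthetic import make_connectome

    return make_connectome(n_regions=8, n_modules=2, density=0.3, seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
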