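import numpy as np
import pytest

from t1rho.core import AcquisitionProtocol
from t1rho.phantom import DEFAULT_PROTOCOL, PhantomSpec, generate_cohort, make_t1rho_field


@pytest.fixture(scope="session")
def protocol() -> AcquisitionProtocol:
    return DEFAULT_PROTOCOL


@pytest.fixture(scope="session")
def noise_free_spec() -> PhantomSpec:
    return PhantomSpec(snr=np.inf, seed=7)


@pytest.fixture(scope="session")
def noise_free_phantom(noise_free_spec):
    """(t1rho field, ROI) of one noise-free phantom subject."""
    return make_t1rho_field(noise_free_spec)


@pytest.fixture(scope="session")
def tiny_cohort(protocol):
    """Two noisy phantom subjects shared across tests."""
    return generate_cohort(2, PhantomSpec(snr=30.0), protocol, seed=11)
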