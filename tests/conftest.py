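import numpy as np
import pytest

from orthosr.phantom import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def phantom96():
    """One 96^3 1 mm head phantom (volume, labels), shared across tests."""
    return make_phantom(PhantomSpec(seed=7, size=96))


@pytest.fixture(scope="session")
def phantom64():
    """A smaller phantom for registration tests."""
    return make_phantom(PhantomSpec(seed=11, size=64))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
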