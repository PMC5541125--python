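import numpy as np
import pytest

from fluororeg.config import default_carm, default_fiducial
from fluororeg.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def carm():
    return default_carm()


@pytest.fixture(scope="session")
def fiducial():
    return default_fiducial()


@pytest.fixture(scope="session")
def scene():
    """One deterministic clean phantom scene shared across the session."""
    return generate_phantom(PhantomSpec(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
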