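import numpy as np
import pytest

from hemifusion import CompartmentSpec, MaterialParams


@pytest.fixture(scope="session")
def params():
    """The reference monolayer parameter set used throughout."""
    return MaterialParams()


@pytest.fixture(scope="session")
def flat():
    return CompartmentSpec(kind="flat")


@pytest.fixture(scope="session")
def sphere20():
    return CompartmentSpec(kind="sphere", R_c=20.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)
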