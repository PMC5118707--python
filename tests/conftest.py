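import numpy as np
import pytest

from beadmill import design


@pytest.fixture(scope="session")
def table1():
    return design.table1_fixture()


@pytest.fixture(scope="session")
def ccd4():
    """A fresh 4-factor CCD with the packaged factor coding (no responses)."""
    return design.build_ccd(design.TABLE1_FACTORS)


@pytest.fixture(scope="session")
def axial_bounds():
    a = design.DEFAULT_ALPHA
    return [(f.decode(-a), f.decode(a)) for f in design.TABLE1_FACTORS]


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
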