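import numpy as np
import pytest

import sparkfiber as sf
from sparkfiber import cell_sim as cs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """Smallest lattice that still has distinct transverse/longitudinal axes."""
    return sf.default_config(nx=3, ny=3, nz=6)


@pytest.fixture
def small_config():
    return sf.default_config(nx=4, ny=4, nz=10)


@pytest.fixture
def gating_params():
    return sf.GatingParams()


@pytest.fixture
def transport_params():
    return sf.TransportParams()
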