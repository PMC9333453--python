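import numpy as np
import pytest

from neurores import models as M
from neurores.network import settled_state


@pytest.fixture(scope="session")
def naph_rest():
    """Settled subthreshold rest of the I_Na,p+I_h model at its
    standard bias."""
    return settled_state(M.NapHParams(), -1.85)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
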