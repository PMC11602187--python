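import numpy as np
import pytest

from pcpsim import KineticParams


@pytest.fixture
def params():
    """Default non-dimensional kinetics (beta0 = gamma = 1, k = 2)."""
    return KineticParams()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
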