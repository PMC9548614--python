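import numpy as np
import pytest

from ttfs import SchemeSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def rnom20():
    """The worked reference R-NoM readout: M=20, N=W=10."""
    return SchemeSpec("rnom", 20, 10, 10)


@pytest.fixture
def nom20():
    return SchemeSpec("nom", 20, 10, 10)


@pytest.fixture
def roc10():
    """The reconstructed speed-accuracy ROC readout: M=10, m=0.8."""
    return SchemeSpec("roc", 10, m=0.8)
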