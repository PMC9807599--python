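import numpy as np
import pytest

from smrbci.montage import BCI_CHANNELS, MontageLayout


@pytest.fixture(scope="session")
def montage():
    return MontageLayout.standard()


@pytest.fixture(scope="session")
def bci_montage():
    return MontageLayout.standard(BCI_CHANNELS)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
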