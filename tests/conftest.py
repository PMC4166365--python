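import numpy as np
import pytest

from gammasnap.spiking import SpikingParams


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20140917)


@pytest.fixture(scope="session")
def fast_spiking_params():
    """Reference spiking parameters with the short default duration."""
    return SpikingParams.defaults()
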