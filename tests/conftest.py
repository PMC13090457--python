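import numpy as np
import pytest

from embolimetry import BinaryMask


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def make_random_mask(rng, shape, p=0.5, spacing_mm=0.1):
    """Random mask with guaranteed background on every grid face."""
    data = rng.random(shape) < p
    data[0] = data[-1] = False
    data[:, 0] = data[:, -1] = False
    data[:, :, 0] = data[:, :, -1] = False
    return BinaryMask(data, spacing_mm)
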