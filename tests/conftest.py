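import numpy as np
import pytest
from hypothesis import settings

from echotex.io import QuantizedImage

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")


def make_quantized(levels, bits=6, mask=None):
    """Wrap a raw level grid as a QuantizedImage for worked examples."""
    levels = np.asarray(levels, dtype=np.int64)
    if mask is None:
        mask = np.ones_like(levels, dtype=bool)
    out = np.where(mask, levels, -1)
    return QuantizedImage(levels=out, bits=bits, mask=np.asarray(mask, bool), mu=0.0, sigma=1.0)


@pytest.fixture
def worked_image():
    """The 3x3 grid used for hand-checked GLCM/RLM values."""
    return np.array([[0, 0, 1], [0, 1, 1], [2, 2, 2]])


@pytest.fixture
def rng():
    return np.random.default_rng(20210611)
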