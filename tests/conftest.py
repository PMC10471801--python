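import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def rect_mask():
    """A 100x40 axis-aligned Soil rectangle inside a 160x200 frame."""
    mask = np.zeros((160, 200), dtype=np.uint8)
    mask[60:100, 50:150] = 2      # 40 rows x 100 cols
    return mask
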