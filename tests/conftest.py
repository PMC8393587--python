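import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_binary_mask(rng, shape, p=0.4, require_both=True):
    """Random binary mask guaranteed to contain both values."""
    for _ in range(100):
        m = (rng.random(shape) < p).astype(np.float64)
        if not require_both or (m.any() and not m.all()):
            return m
    raise AssertionError("could not draw a two-valued mask")
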