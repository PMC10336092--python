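import numpy as np
import pytest

from forestfrag import BinaryForestMap


@pytest.fixture
def checkerboard_map():
    """8x8 alternating forest/non-forest map, 10 m pixels."""
    v = np.indices((8, 8)).sum(axis=0) % 2
    return BinaryForestMap(v.astype(np.int8), pixel_size=10.0, epoch=2000)


@pytest.fixture
def random_window():
    """Factory for random binary windows with a fixed-seed generator."""
    rng = np.random.default_rng(20260928)

    def make(nrows=20, ncols=20, p=0.5):
        return (rng.random((nrows, ncols)) < p).astype(np.int8)

    return make
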