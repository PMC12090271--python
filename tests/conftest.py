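import numpy as np
import pytest

from dart2.tracking import PixelMask, TubeGeometry


def mask_from_offsets(offsets, L, odorant_end="low"):
    """Mask with one flagged pixel per listed odorant-end offset.

    Each entry gets its own row, so repeated offsets keep their
    multiplicity in the pixel statistics.
    """
    offsets = list(offsets)
    geometry = TubeGeometry(0, L - 1, odorant_end)
    flags = np.zeros((max(len(offsets), 1), L), dtype=bool)
    for i, off in enumerate(offsets):
        col = off if odorant_end == "low" else L - 1 - off
        flags[i, col] = True
    return PixelMask(flags=flags, geometry=geometry)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
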