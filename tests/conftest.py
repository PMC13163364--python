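import numpy as np
import pytest

from priorseg import BinaryMask, GridVolume


@pytest.fixture(scope="session")
def toy_cohort():
    """Three quantized 3x8x8 (vol, mask) pairs with an off-center blob each."""
    rng = np.random.default_rng(42)
    pairs = []
    for i in range(3):
        mask = np.zeros((3, 8, 8), dtype=np.uint8)
        cy, cx = 3 + (i % 2), 3 + (i // 2)
        mask[:, cy - 1 : cy + 2, cx - 1 : cx + 2] = 1
        vol = rng.integers(0, 8, size=(3, 8, 8))
        vol[mask.astype(bool)] += 8  # separable-ish foreground
        pairs.append(
            (
                GridVolume(vol.astype(np.int32), spacing=(4, 1, 1)),
                BinaryMask(mask, spacing=(4, 1, 1)),
            )
        )
    return pairs


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_mask(rng, shape, p=0.4):
    """Random non-empty binary mask."""
    while True:
        m = (rng.random(shape) < p).astype(np.uint8)
        if m.any():
            return m
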