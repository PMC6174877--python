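import numpy as np
import pytest

from colorcard import ChipColorMatrix
from colorcard.synthetic import CLASSIC_CHIP_COLORS


def random_chips(rng: np.random.Generator, k: int = 24, image_id: str = "rand") -> ChipColorMatrix:
    """A random full-rank chip matrix with values well inside [0, 255]."""
    values = rng.uniform(10.0, 245.0, size=(k, 3))
    return ChipColorMatrix(values, [f"chip_{i:02d}" for i in range(k)], image_id)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def canonical_chips():
    ids = [f"chip_{i:02d}" for i in range(24)]
    return ChipColorMatrix(CLASSIC_CHIP_COLORS.copy(), ids, "canonical")
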