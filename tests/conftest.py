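import numpy as np
import pytest

from rhythmpencil import SamplingGrid


@pytest.fixture
def grid24() -> SamplingGrid:
    """The canonical 48-h design: CT0..CT46 at a 2-h step."""
    return SamplingGrid(0.0, 2.0, 24)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
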