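import numpy as np
import pytest

from motcount.geometry import BoundingBox


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_box(rng, span: float = 200.0) -> BoundingBox:
    x, y = rng.uniform(0, span, size=2)
    w, h = rng.uniform(1.0, span / 2, size=2)
    return BoundingBox(x, y, w, h)


@pytest.fixture
def random_box_pairs(rng):
    return [(random_box(rng), random_box(rng)) for _ in range(1000)]
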