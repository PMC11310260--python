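import numpy as np
import pytest

from musuppress.core import ConditionSegment, Recording
from musuppress.synthetic import make_head_model


@pytest.fixture(scope="session")
def model40():
    """64-channel, 40-vertex head model used across test modules."""
    return make_head_model(40, 64, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_recording(rng):
    data = rng.standard_normal((8, 1024))
    return Recording(data, 128.0, [f"E{i:02d}" for i in range(8)],
                     condition="balls", subject="sub00", session="pre")


def make_segment(data: np.ndarray, fs: float) -> ConditionSegment:
    names = [f"E{i:02d}" for i in range(data.shape[0])]
    return ConditionSegment(np.asarray(data, dtype=float), fs, names)
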