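import numpy as np
import pytest

from mesopipe.core_io import ImageStack, RecordingMeta


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_stack(data, frame_rate_hz=10.0, channel="fluo", **meta_kwargs):
    data = np.asarray(data, dtype=float)
    meta = RecordingMeta(
        frame_rate_hz=frame_rate_hz,
        height_px=data.shape[1],
        width_px=data.shape[2],
        n_frames=data.shape[0],
        channel_name=channel,
        **meta_kwargs,
    )
    return ImageStack(data, meta)


@pytest.fixture
def stack_factory():
    return make_stack


@pytest.fixture
def random_stack(rng):
    return make_stack(rng.normal(1.0, 0.1, size=(50, 8, 8)))
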