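import numpy as np
import pytest

from bayescoloc.images import ChannelRaster, MultiChannelImage


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


def make_image(arrays, name="img") -> MultiChannelImage:
    """Build a MultiChannelImage from a list of 2-D arrays in [0, 1]."""
    channels = tuple(
        ChannelRaster(i + 1, np.asarray(a, dtype=float)) for i, a in enumerate(arrays)
    )
    return MultiChannelImage(name, channels)


@pytest.fixture
def two_channel_image(rng):
    """64x64 two-channel image: bright correlated square on dark noise."""
    h = w = 64
    a = 0.05 + 0.01 * rng.standard_normal((h, w))
    b = 0.05 + 0.01 * rng.standard_normal((h, w))
    z = rng.standard_normal((h, w))
    a[16:48, 16:48] = 0.6 + 0.1 * z[16:48, 16:48]
    b[16:48, 16:48] = 0.6 + 0.1 * (
        0.8 * z[16:48, 16:48]
        + 0.6 * rng.standard_normal((32, 32))
    )
    return make_image([np.clip(a, 0, 1), np.clip(b, 0, 1)])
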