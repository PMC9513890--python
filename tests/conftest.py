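import numpy as np
import pytest

from aneuseg.imaging import BinaryMask, VolumeImage


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def small_volume(rng):
    data = rng.normal(size=(16, 16, 16)).astype(np.float32)
    return VolumeImage(data=data, spacing=(0.5, 0.5, 0.5))


def random_mask(rng, shape=(10, 10, 10), p=0.1, spacing=(1.0, 1.0, 1.0)):
    data = (rng.random(shape) < p).astype(np.uint8)
    return BinaryMask(data=data, spacing=spacing)
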