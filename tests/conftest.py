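import numpy as np
import pytest

from clib.synthetic import SyntheticSpec, generate_dataset
from clib.views import AugmentationPolicy, CropGeometry, ImageBatch


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def geometry():
    return CropGeometry(output_size=(32, 32))


@pytest.fixture
def identity_policy():
    return AugmentationPolicy.identity()


@pytest.fixture
def tiny_dataset():
    """20 images, 5 classes, deterministic."""
    return generate_dataset(SyntheticSpec(per_class=4, seed=7))


@pytest.fixture
def tiny_batch(tiny_dataset):
    return ImageBatch(pixels=tiny_dataset.images.pixels[:8],
                      labels=tiny_dataset.labels[:8])


def checkerboard(h=64, w=64, c=3):
    """Deterministic structured image with a distinct center motif."""
    yy, xx = np.mgrid[0:h, 0:w]
    img = ((yy // 4 + xx // 4) % 2).astype(float)
    img = np.repeat(img[..., None], c, axis=2)
    img[h // 2 - 4 : h // 2 + 4, w // 2 - 4 : w // 2 + 4] = 0.5
    return img
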