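import numpy as np
import pytest

from bladderwall.imaging import GrayImage
from bladderwall.levelset_seg import segment_wall
from bladderwall.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free reference phantom: inner radius 22 px, wall 5 px."""
    return generate_phantom(PhantomSpec(wall_thickness_mean=5, noise_sigma=0, seed=2))


@pytest.fixture(scope="session")
def noisy_phantom():
    """Same geometry with additive noise at 5% of the 0-255 range."""
    return generate_phantom(PhantomSpec(wall_thickness_mean=5, noise_sigma=12.75, seed=2))


@pytest.fixture(scope="session")
def clean_segmentation(clean_phantom):
    center = ((clean_phantom.spec.image_size - 1) / 2,) * 2
    return segment_wall(clean_phantom.image, center, 5.0)


@pytest.fixture(scope="session")
def noisy_segmentation(noisy_phantom):
    center = ((noisy_phantom.spec.image_size - 1) / 2,) * 2
    return segment_wall(noisy_phantom.image, center, 5.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_image(pixels, spacing=(1.0, 1.0)):
    return GrayImage(np.asarray(pixels, dtype=float), spacing)
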