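import numpy as np
import pytest

from mriqa.masks import background_mask, build_eye_mask, build_ring_mask, normalize_map
from mriqa.phantom import PhantomSpec, generate_head_phantom
from mriqa.pipeline import default_phantom_eye_boxes, head_z_extent

SMALL_SHAPE = (62, 64, 64)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free phantom: every ASF must be exactly zero on it."""
    return generate_head_phantom(PhantomSpec(shape=SMALL_SHAPE, noise_sd=0.0, seed=1))


@pytest.fixture(scope="session")
def noisy_phantom():
    return generate_head_phantom(PhantomSpec(shape=SMALL_SHAPE, seed=2))


@pytest.fixture(scope="session")
def eye_boxes():
    return default_phantom_eye_boxes(SMALL_SHAPE)


@pytest.fixture(scope="session")
def clean_masks(clean_phantom, eye_boxes):
    """(background, eye, ring) masks for the clean phantom."""
    vol, maps, tp = clean_phantom
    bg = background_mask(normalize_map(maps["background"], tp, cval=1.0), tp)
    eye = build_eye_mask(bg, eye_boxes, tp)
    ring = build_ring_mask(bg, head_z_extent(maps))
    return bg, eye, ring


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
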