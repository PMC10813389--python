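import numpy as np
import pytest

from cecounter.dataset_io import AnnotatedImage
from cecounter.synthetic import SceneSpec, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_scene():
    """A deterministic middle-density 96x96 scene."""
    spec = SceneSpec.for_regime("middle", seed=7, width_px=96, height_px=96)
    return generate_scene(spec)


@pytest.fixture
def annotated(small_scene) -> AnnotatedImage:
    return small_scene.to_annotated("scene7")


def tiny_record(image_id="t", width=20, height=12, centers=((3.0, 4.0), (10.0, 7.0))):
    rng = np.random.default_rng(abs(hash(image_id)) % (2 ** 31))
    pixels = rng.integers(0, 256, size=(height, width), dtype=np.uint8)
    return AnnotatedImage(image_id=image_id, pixels=pixels, centers=np.array(centers))
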