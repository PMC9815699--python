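import numpy as np
import pytest

from weeddet.synthdata import SceneParams, generate_corpus, generate_scene


@pytest.fixture(scope="session")
def small_scene_params():
    """Compact scene for fast per-test generation."""
    return SceneParams(image_size=(96, 96), n_crops=3, n_weeds=2,
                       crop_radius_range=(7.0, 10.0),
                       weed_radius_range=(2.5, 4.5), seed=7)


@pytest.fixture(scope="session")
def field_scene():
    """One default-sized scene at the corpus ratio (17 crops, 3 weeds)."""
    return generate_scene(SceneParams(seed=42), image_id="field-0")


@pytest.fixture(scope="session")
def weed_subimage():
    """A weed-only sub-image with six weeds, as used for patch extraction."""
    return generate_scene(
        SceneParams(seed=11, n_crops=0, n_weeds=6), image_id="sub-0")


@pytest.fixture(scope="session")
def small_corpus(small_scene_params):
    """Ten 96x96 scenes at aggregate crop:weed = 3:2."""
    images, manifest = generate_corpus(10, small_scene_params, (3, 2))
    return images, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
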