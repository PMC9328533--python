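import numpy as np
import pytest

from svimon.scenegen import SceneParams, SeasonalModel, generate_scene, generate_site_album


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_scene():
    return generate_scene(SceneParams(height=64, width=64, veg_fraction=0.3, seed=7))


@pytest.fixture
def tiny_scene():
    return generate_scene(SceneParams(height=32, width=32, veg_fraction=0.25, seed=3))


@pytest.fixture(scope="session")
def small_album():
    """24 noise-free quarterly scenes of one site (6 years x 4 quarters)."""
    return generate_site_album(
        "siteA",
        SeasonalModel(base_fraction=0.3, amplitude=0.1, noise_sd=0.0),
        range(2015, 2021),
        per_quarter=1,
        scene=SceneParams(height=64, width=64, seed=11),
    )


def random_mask(rng, shape=(16, 16), n_classes=3):
    return rng.integers(0, n_classes, size=shape).astype(np.uint8)
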