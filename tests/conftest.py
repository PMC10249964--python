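import numpy as np
import pytest

from ricepheno import GrowthGroundTruth, render_plant_image, segment_plant


@pytest.fixture(scope="session")
def default_gt() -> GrowthGroundTruth:
    return GrowthGroundTruth(plant_id="fixture")


@pytest.fixture(scope="session")
def rendered_mid_season(default_gt):
    """One post-heading render (day 120) with its true masks."""
    img, truth = render_plant_image(default_gt, day=120, seed=42)
    return img, truth


@pytest.fixture(scope="session")
def segmented_mid_season(rendered_mid_season):
    img, truth = rendered_mid_season
    return img, truth, segment_plant(img)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
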