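import numpy as np
import pytest

from tiltpool.geometry import ViewingGeometry
from tiltpool.synthetic import SceneRecipe, generate_scene


@pytest.fixture(scope="session")
def geom128():
    return ViewingGeometry(pixel_scale=1.0, fixation_distance_m=10.0,
                           image_size=(128, 128))


@pytest.fixture(scope="session")
def geom160():
    return ViewingGeometry(pixel_scale=1.0, fixation_distance_m=10.0,
                           image_size=(160, 160))


@pytest.fixture(scope="session")
def plane_scenes(geom128):
    """Six rendered single-plane stereo scenes with analytic groundtruth."""
    uni = np.ones(24) / 24
    out = []
    for seed in range(6):
        recipe = SceneRecipe(seed=seed, n_facets=1, tilt_prior_weights=uni,
                             facet_border_margin_px=0)
        out.append(generate_scene(recipe, geom128))
    return out


@pytest.fixture(scope="session")
def mosaic_scene(geom160):
    """One rendered planar-mosaic scene (uniform tilt prior)."""
    recipe = SceneRecipe(seed=11, n_facets=10,
                         tilt_prior_weights=np.ones(24) / 24)
    return generate_scene(recipe, geom160)
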