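"""Shared fixtures: synthetic scenes rendered once per session."""

import numpy as np
import pytest

from depthplate.synthetic import FoodItem, SceneSpec, generate_scene


@pytest.fixture(scope="session")
def hemisphere_scene():
    """Noiseless hemispherical dome, r = 30 mm, rendered at 1 mm/px."""
    dome = FoodItem("dome", radius_mm=30.0, peak_height_mm=30.0)
    return generate_scene(SceneSpec(items=(dome,), frames=1, seed=0))


@pytest.fixture(scope="session")
def empty_scene():
    """Empty plate, noiseless, single frame."""
    return generate_scene(SceneSpec(items=(), frames=1, seed=0))


@pytest.fixture(scope="session")
def red_dome_scene():
    """Saturated red dome on a white plate; the colour baseline's home turf."""
    dome = FoodItem("dome", radius_mm=40.0, peak_height_mm=25.0, color=(190, 30, 25))
    return generate_scene(SceneSpec(items=(dome,), frames=1, seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
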