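import numpy as np
import pytest

from fruitherm import (SceneSpec, TemperatureFieldSpec, generate_scene,
                       default_scene_camera)


@pytest.fixture(scope="session")
def default_scene():
    """One default synthetic tree with ground truth (seed fixed)."""
    spec = SceneSpec(seed=3)
    cloud, truth = generate_scene(spec)
    return spec, cloud, truth


@pytest.fixture(scope="session")
def scene_camera(default_scene):
    spec, _, _ = default_scene
    return default_scene_camera(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
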