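import numpy as np
import pytest

from gantryvision.geometry import CameraModel, CameraPose, WorldPoint


@pytest.fixture(scope="session")
def default_model() -> CameraModel:
    return CameraModel()


@pytest.fixture(scope="session")
def small_model() -> CameraModel:
    """Down-scaled render resolution with the production FOV."""
    return CameraModel(width=200, height=150)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_visible_pose(rng: np.random.Generator) -> CameraPose:
    """A pose inside the travel volume looking broadly downward."""
    return CameraPose(
        WorldPoint(rng.uniform(150, 1000), rng.uniform(150, 700), rng.uniform(250, 700)),
        pan=rng.uniform(0, 360),
        tilt=rng.uniform(5, 85),
    )
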