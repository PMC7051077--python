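"""Shared fixtures: spectral scene, calibrated cameras and characterizations.

Session-scoped because the illuminant solves and characterization fits are
deterministic and reused by many tests.
"""

import numpy as np
import pytest

from scbkit.colorimetry import default_grid
from scbkit.pipeline import characterize_camera
from scbkit.simulate import (
    calibrate_gain,
    default_camera,
    illuminant_preset,
    luther_camera,
    scale_preset_to_signal,
)

EXPOSURE = 1 / 30


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def screen(grid):
    return illuminant_preset("screen_white", grid)


@pytest.fixture(scope="session")
def camera(grid, screen):
    """Noiseless generic camera calibrated so a white patch under the
    screen alone reaches 0.45."""
    cam = default_camera(grid).noiseless()
    cam = calibrate_gain(cam, screen, EXPOSURE, target=0.45)
    return cam


@pytest.fixture(scope="session")
def screen_scaled(screen, camera):
    return scale_preset_to_signal(screen, camera, EXPOSURE, 0.45)


@pytest.fixture(scope="session")
def characterization(camera, screen_scaled):
    return characterize_camera(camera, screen_scaled, exposure=EXPOSURE)


@pytest.fixture(scope="session")
def luther(grid, screen):
    cam = luther_camera(grid).noiseless()
    return calibrate_gain(cam, screen, EXPOSURE, target=0.45)


@pytest.fixture(scope="session")
def luther_characterization(luther, screen_scaled):
    return characterize_camera(luther, screen_scaled, exposure=EXPOSURE)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
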