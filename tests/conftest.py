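"""Shared fixtures: phantom scene, calibration and simulated exams.

Everything is generated programmatically and deterministically; the phantom
scene and rendered exams are session-scoped because they are the expensive
shared inputs of many tests.
"""

import numpy as np
import pytest

from autorsa.geometry import PinholeCamera, nominal_stereo_calibration
from autorsa.phantom import default_calibration, make_phantom, simulate_exam
from autorsa.registration import RegistrationConfig


@pytest.fixture(scope="session")
def scene():
    return make_phantom(7)


@pytest.fixture(scope="session")
def calib():
    return default_calibration()


@pytest.fixture(scope="session")
def clean_exam(scene, calib):
    """Noise-free stereo exam of the phantom at its base pose."""
    return simulate_exam(scene, calib, None, None, seed=3)


@pytest.fixture(scope="session")
def overhead_camera():
    """Single vertical source at the study's source-to-image distance,
    full-scale pixel pitch, detector window centered under the source."""
    pitch = 0.16
    rows = cols = 512
    H = np.array([[pitch, 0.0, -pitch * (cols - 1) / 2.0],
                  [0.0, -pitch, pitch * (rows - 1) / 2.0],
                  [0.0, 0.0, 1.0]])
    return PinholeCamera(np.array([0.0, 0.0, 1600.0]), H, pitch, (rows, cols))


def fast_registration_config(renderer: str, seed: int = 0,
                             **overrides) -> RegistrationConfig:
    """Quarter-scale phantom registration schedule used throughout the tests:
    mask radii scaled to the quarter-resolution detector, a compact global
    search and the standard local refinement."""
    kw = dict(bounds_mm=3.0, bounds_deg=3.0, global_budget=150, population=35,
              local_max_evals=600, seed=seed, dynamic_radius_px=4,
              fixed_radius_px=2, renderer=renderer)
    kw.update(overrides)
    return RegistrationConfig(**kw)


@pytest.fixture(scope="session")
def small_stereo():
    """Coarse stereo geometry for fast marker/geometry tests."""
    return nominal_stereo_calibration(image_shape=(256, 256),
                                      pixel_pitch=1.0)
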