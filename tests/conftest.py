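import numpy as np
import pytest

from wristsim import (
    build_default_wrist,
    default_marker_sets,
    make_biplanar_rig,
)


@pytest.fixture(scope="session")
def left_model():
    return build_default_wrist("left")


@pytest.fixture(scope="session")
def rig():
    return make_biplanar_rig()


@pytest.fixture(scope="session")
def marker_sets():
    return default_marker_sets()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rotation(rng, max_angle_deg=80.0):
    """Random rotation with bounded geodesic angle (gimbal-safe range)."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(-max_angle_deg, max_angle_deg))
    from scipy.spatial.transform import Rotation

    return Rotation.from_rotvec(angle * axis).as_matrix()
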