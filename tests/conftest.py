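import numpy as np
import pytest

from podsplit3d import (
    CameraIntrinsics,
    Extrinsics,
    LightPlane,
)


@pytest.fixture
def printed_intrinsics():
    """The rig's published intrinsic matrix (focal 1027 px, principal point
    (1224, 972))."""
    return CameraIntrinsics(fx=1027.0, fy=1027.0, u0=1224.0, v0=972.0)


@pytest.fixture
def printed_plane():
    """The rig's published light-plane coefficients."""
    return LightPlane(a=0.000022, b=-0.000003, c=0.001877, d=1.0)


@pytest.fixture
def printed_extrinsics():
    """The rig's published extrinsics (R is orthonormal only to ~1e-3,
    which triggers the documented warning)."""
    R = np.array([
        [-0.7651, -0.6438, -0.0116],
        [0.6439, -0.7651, -0.0003],
        [-0.0087, -0.0077, 0.9999],
    ])
    T = np.array([30.3430, 12.0417, 533.1570])
    with pytest.warns(UserWarning, match="orthonormal"):
        ext = Extrinsics(R=R, T=T)
    return ext


@pytest.fixture
def rng():
    return np.random.default_rng(20240714)
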