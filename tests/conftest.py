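import numpy as np
import pytest

from nucleoflux.meshing import build_axisymmetric_mesh, build_octant_mesh


@pytest.fixture(scope="session")
def octant_coarse():
    """Small octant mesh shared by 3D mechanics tests."""
    return build_octant_mesh(h=2.0)


@pytest.fixture(scope="session")
def axisym_coarse():
    """Small axisymmetric mesh shared by 2D tests."""
    return build_axisymmetric_mesh(h=0.7)


@pytest.fixture(scope="session")
def axisym_default():
    return build_axisymmetric_mesh()


def rotation_about_z(angle_deg: float) -> np.ndarray:
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
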