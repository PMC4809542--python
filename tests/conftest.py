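import numpy as np
import pytest

from uteromag.cell_dynamics import DEFAULT_CELL
from uteromag.fiber_tissue import build_fiber_field, conductivity_tensors
from uteromag.geometry import GeometrySpec, make_spherical_uterus


@pytest.fixture(scope="session")
def params():
    """Published myometrium cell parameters."""
    return DEFAULT_CELL


@pytest.fixture(scope="session")
def sphere_coarse():
    """Level-3 mid-wall uterus sphere (642 vertices)."""
    return make_spherical_uterus(GeometrySpec(subdivisions=3))


@pytest.fixture(scope="session")
def sphere_fine():
    """Level-4 mid-wall uterus sphere (2562 vertices)."""
    return make_spherical_uterus(GeometrySpec(subdivisions=4))


@pytest.fixture(scope="session")
def vertical_fibers_coarse(sphere_coarse):
    return build_fiber_field(sphere_coarse, fixed_angle=0.0)


@pytest.fixture(scope="session")
def tensors_coarse(sphere_coarse, vertical_fibers_coarse):
    return conductivity_tensors(vertical_fibers_coarse)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160328)
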