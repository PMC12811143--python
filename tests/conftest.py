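import numpy as np
import pytest

from cardiomorph.morphometry import (
    COMPACT_MYOCARDIUM,
    IVS,
    LV_LUMEN,
    RV_LUMEN,
    SectionLabelStack,
)
from cardiomorph.synthetic import (
    BoundaryPhantomSpec,
    HeartPhantomSpec,
    HoleSpec,
    make_boundary_volume,
    make_section_stack,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def boundary_volume():
    """Noiseless field-mode boundary phantom, centre +70 um, width 20 um."""
    spec = BoundaryPhantomSpec(
        shape_px=(4, 16, 256),
        voxel_size_um=(10.0, 2.0, 2.0),
        boundary_center_um=70.0,
        boundary_width_um=20.0,
    )
    return make_boundary_volume(spec)


@pytest.fixture(scope="session")
def holed_stack():
    """Section stack with one mid-muscular cylindrical hole, r = 50 um."""
    spec = HeartPhantomSpec(
        pixel_size_um=2.0,
        n_slices=30,
        hole_specs=(HoleSpec(z_center_um=75.0, y_center_um=0.0, radius_um=50.0),),
    )
    return make_section_stack(spec)


@pytest.fixture
def slab_wall_stack():
    """Two straight compact walls of 50 um (25 px at 2 um) flanking an IVS."""
    lab = np.zeros((3, 300, 120), np.uint8)
    lab[:, 10:290, 10:35] = COMPACT_MYOCARDIUM
    lab[:, 10:290, 85:110] = COMPACT_MYOCARDIUM
    lab[:, 10:290, 58:62] = IVS
    lab[:, 10:290, 36:56] = RV_LUMEN
    lab[:, 10:290, 64:84] = LV_LUMEN
    return SectionLabelStack(lab, pixel_size_um=2.0)
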