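import numpy as np
import pytest

from weplrange.calibration import CalibrationTable
from weplrange.raytrace import BeamGeometry, SPImage


@pytest.fixture
def default_table():
    return CalibrationTable.default()


@pytest.fixture
def water_image():
    """Uniform water: 60 x 40 pixels at 1 mm spacing, grid-centred."""
    return SPImage(values=np.ones((60, 40)), pixel_spacing=(1.0, 1.0))


@pytest.fixture
def anterior_parallel():
    return BeamGeometry(gantry_angle=0.0, source_axis_distance=None)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
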