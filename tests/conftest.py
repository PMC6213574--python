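import numpy as np
import pytest

from toflaue import geometry as g
from toflaue import pipeline as pl


@pytest.fixture(scope="session")
def reduction():
    """One full end-to-end reduction of the study fixture, shared by all
    tests that score pipeline stages."""
    return pl.reduce_fixture(seed=11)


@pytest.fixture
def simple_detector():
    return g.DetectorGeometry(detector_id=0, n_pixels_x=64, n_pixels_y=64,
                              pixel_pitch=13.3 / 64, L2=49.0)


@pytest.fixture
def tilted_detector():
    return g.DetectorGeometry(
        detector_id=1, n_pixels_x=64, n_pixels_y=64, pixel_pitch=13.3 / 64,
        L2=49.0, Rot_x=-30.0, Rot_y=55.0, R_x=0.7, R_y=-0.4, R_z=5.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
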