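import numpy as np
import pytest

from sftag.geometry import BandGeometry
from sftag.synthetic import SyntheticVideoSpec, make_video
from sftag.tagging import Condition, TagSpec


@pytest.fixture(scope="session")
def default_geometry():
    return BandGeometry()


@pytest.fixture(scope="session")
def natural_clip():
    """One 3 s, 30 fps, 128x128 natural-statistics clip shared across tests."""
    return make_video(SyntheticVideoSpec(seed=11))


@pytest.fixture(scope="session")
def cond1_spec():
    return TagSpec(condition=Condition.COND1)


def oblique_grating(shape, cycles_x, cycles_y, amplitude=0.3, offset=0.5):
    """Integer-cycle grating; orientation set by the cycle counts."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    return offset + amplitude * np.sin(2 * np.pi * (cycles_x * xx / w + cycles_y * yy / h))
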