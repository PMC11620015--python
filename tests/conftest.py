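import numpy as np
import pytest

from ccfdgrid import BinaryMask, EnFaceImage, ScanGeometry
from ccfdgrid.synthdata import SimulationConfig, simulate_eye


@pytest.fixture(scope="session")
def geometry_500():
    return ScanGeometry.create(500, 500, 12.0)


@pytest.fixture(scope="session")
def plain_eye():
    """A lesion-free, drusen-free synthetic eye (flow, structure, retina,
    masks, truth)."""
    cfg = SimulationConfig(seed=3, drusen=(), lesions=())
    return simulate_eye(cfg)


@pytest.fixture(scope="session")
def drusen_eye():
    """Default synthetic eye with drusen and lesion masks."""
    cfg = SimulationConfig(seed=7)
    return simulate_eye(cfg), cfg


def make_image(pixels, spacing_um=12.0, **kwargs):
    pixels = np.asarray(pixels, dtype=float)
    h, w = pixels.shape
    return EnFaceImage(pixels, ScanGeometry.create(w, h, spacing_um), **kwargs)
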