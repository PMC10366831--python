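import numpy as np
import pytest

from vctdbt.geometry import DetectorSpec
from vctdbt.phantom import LabelVolume


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def fine_detector():
    """Detector with pitch finer than 1 mm voxels (localization tests)."""
    return DetectorSpec(pixel_pitch_mm=0.5, n_u=160, n_v=128, gap_mm=25.0)


@pytest.fixture
def coarse_detector():
    return DetectorSpec(pixel_pitch_mm=2.0, n_u=60, n_v=76, gap_mm=25.0)


@pytest.fixture
def random_labels(rng):
    return LabelVolume(labels=rng.integers(0, 3, (10, 10, 10)).astype(np.uint8),
                       voxel_mm=1.0)
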