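import numpy as np
import pytest

from habitatmsi.preprocess import RegionMask, Volume3D


@pytest.fixture
def box_mask():
    """10x10x10 grid with a 6x6x6 solid ROI."""
    m = np.zeros((10, 10, 10), dtype=bool)
    m[2:8, 2:8, 2:8] = True
    return RegionMask(m, region="GTVp")


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def make_volume(values, channel="T1"):
    return Volume3D(np.asarray(values, dtype=float), channel=channel)


@pytest.fixture
def random_volume(box_mask, rng):
    return make_volume(rng.normal(size=box_mask.values.shape))
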