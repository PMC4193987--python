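import numpy as np
import pytest

from anat3d.phantom import PhantomSpec, make_ct_phantom
from anat3d.volume_io import Mask, Volume


@pytest.fixture(scope="session")
def default_phantom():
    """Noise-free temporal-bone phantom with its ground-truth labels."""
    return make_ct_phantom(PhantomSpec(), seed=0)


@pytest.fixture(scope="session")
def ramp_volume():
    """A volume containing every integer HU value in [-1024, 3500]."""
    values = np.arange(-1024, 3501, dtype=np.int16)
    pad = (-(-len(values) // 100)) * 100 - len(values)
    data = np.concatenate([values, np.full(pad, -1024, dtype=np.int16)])
    return Volume(data.reshape(100, -1, 1), spacing=(0.15, 0.15, 0.15))


def make_mask(data, spacing=(1.0, 1.0, 1.0)):
    return Mask(np.asarray(data, dtype=bool), spacing)
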