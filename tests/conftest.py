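import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_volume():
    """A 17x17x13 random grayscale volume (odd dims: exact centre voxel)."""
    from capitulum3d import Volume

    data = np.random.default_rng(7).random((17, 17, 13))
    return Volume(data, voxel_size_um=2.75)
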