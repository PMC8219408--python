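import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210422)


@pytest.fixture()
def disc_map():
    """128x128 flat map carrying one 3 nm deep disc of radius 20 px."""
    from memrupt import HeightMap

    h = np.zeros((128, 128))
    rr, cc = np.ogrid[:128, :128]
    h[(rr - 64) ** 2 + (cc - 64) ** 2 <= 20**2] = -3.0
    return HeightMap(h, 4.0)
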