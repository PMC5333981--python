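import numpy as np
import pytest

from vesselbelt import SyntheticLayout


@pytest.fixture(scope="session")
def default_layout():
    return SyntheticLayout()


@pytest.fixture(scope="session")
def default_rois(default_layout):
    return default_layout.to_roi_set()


@pytest.fixture(scope="session")
def render_layout():
    # small domain so rendered fixtures stay ~1000x1000 px
    return SyntheticLayout(
        domain_width=0.5,
        lumen_band_height=0.1,
        tumor_band_height=0.3,
        adjacent_band_height=0.1,
        mpp=0.5,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
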