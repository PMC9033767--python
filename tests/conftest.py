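import numpy as np
import pytest

from slbafm.raster_io import HeightMap


def make_map(heights, pixel_size=10.0, name="test"):
    return HeightMap(heights=np.asarray(heights, float), pixel_size=pixel_size, name=name)


@pytest.fixture
def bimodal_map():
    """60% substrate at 0 ± 0.1 nm, 40% terrace at 4.5 ± 0.1 nm."""
    rng = np.random.default_rng(42)
    h = np.zeros((50, 50))
    h[:20, :] = 4.5
    h += rng.normal(0, 0.1, h.shape)
    return make_map(h)
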