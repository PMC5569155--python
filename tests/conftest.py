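import numpy as np
import pytest
from hypothesis import settings

import swequant as sq

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def lut():
    return sq.build_default_lut()


@pytest.fixture(scope="session")
def phantom_map():
    """Default three-inclusion phantom field with a soft edge."""
    return sq.make_elasticity_field(sq.PhantomScene(), edge_width_mm=0.3)


def smooth_random_map(seed, shape=(120, 160), lo=0.0, hi=180.0, spacing=0.2):
    """Smooth random elasticity field emulating a device-smoothed elastogram."""
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=6)
    f = (f - f.min()) / (f.max() - f.min())
    return sq.ElasticityMap(lo + (hi - lo) * f, np.zeros(shape, bool), spacing, 300.0)
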