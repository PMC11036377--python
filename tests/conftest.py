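import numpy as np
import pytest

from neosynth.phantom import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def smooth_phantom():
    """64³ unfolded phantom: GM is a spherical shell (session-cached)."""
    spec = PhantomSpec((64, 64, 64), 1.0, folding=0.0,
                       cortical_thickness=3.0, seed=1)
    label_map, surfaces = make_phantom(spec)
    return spec, label_map, surfaces


@pytest.fixture(scope="session")
def folded_phantom():
    """Moderately folded 48³ phantom (session-cached)."""
    spec = PhantomSpec((48, 48, 48), 1.0, folding=0.5,
                       cortical_thickness=3.0, seed=3)
    label_map, surfaces = make_phantom(spec)
    return spec, label_map, surfaces


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
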