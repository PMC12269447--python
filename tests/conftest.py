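import numpy as np
import pytest

from roomct.frames import Frame
from roomct.images import CTVolume
from roomct.phantoms import add_texture, make_head_phantom, rasterize


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def coarse_head_volume():
    """Textured head phantom on a coarse 2.5 mm grid: fast registration fixture."""
    spec, iso = make_head_phantom()
    grid = spec.default_grid(spacing=(2.5, 2.5, 2.5), margin=15.0)
    return add_texture(rasterize(spec, grid)), iso


@pytest.fixture(scope="session")
def point_object_volume():
    """Single bright off-center voxel cluster in air: projector test target."""
    vals = np.full((61, 81, 61), -1000.0, dtype=np.float32)
    vol = CTVolume(vals, (-30.0, -40.0, -30.0), (1.0, 1.0, 1.0), Frame.CT)
    vol.values[42, 55, 18] = 20000.0
    return vol, np.asarray(vol.index_to_physical((42, 55, 18)))
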