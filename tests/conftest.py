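import numpy as np
import pytest

from rnatube.synthetic.assembly import AssemblySpec, build_tile_assembly


@pytest.fixture(scope="session")
def small_assembly():
    """A 6-layer, 3-tile-per-layer nanotube with 72-nt tiles."""
    return build_tile_assembly(AssemblySpec(n_layers=6, nt_per_tile=72, seed=1))


@pytest.fixture
def disc_mask():
    def make(radius_px: int, shape=(81, 81)):
        size = shape
        rr, cc = np.indices(size)
        c = (size[0] // 2, size[1] // 2)
        return (rr - c[0]) ** 2 + (cc - c[1]) ** 2 <= radius_px**2

    return make
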