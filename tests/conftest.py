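import numpy as np
import pytest

from nichecast.geo_io import EnvStack, GridGeometry


@pytest.fixture
def geom10():
    """10x10 half-degree grid, top-left at (100E, 40N), all cells valid."""
    return GridGeometry(10, 10, 0.5, 100.0, 40.0)


@pytest.fixture
def stack3(geom10):
    """Three smooth deterministic layers on the 10x10 grid."""
    rng = np.random.default_rng(42)
    lon, lat = geom10.cell_centers()
    layers = {
        "bio01": lat + 0.1 * rng.standard_normal(geom10.shape),
        "bio02": lon - 100.0 + 0.1 * rng.standard_normal(geom10.shape),
        "bio03": rng.standard_normal(geom10.shape),
    }
    return EnvStack(geom10, layers)
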