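import numpy as np
import pandas as pd
import pytest

from irrigrid import WorldConfig, make_world
from irrigrid.grid import Grid, GridGeometry


@pytest.fixture(scope="session")
def small_world():
    """A small multi-region, multi-crop world with constant change ratio."""
    cfg = WorldConfig(grid_height=16, grid_width=16, coarse_factor=8,
                      n_nuts1=2, nuts2_per_nuts1=2, n_crops=4,
                      years=(2010, 2012), seed=11)
    return make_world(cfg)


@pytest.fixture(scope="session")
def region_table():
    return pd.DataFrame({
        "region_id": ["N1", "N2", "N1A", "N1B", "N2A", "N2B"],
        "parent_id": ["", "", "N1", "N1", "N2", "N2"],
        "level": ["NUTS1", "NUTS1", "NUTS2", "NUTS2", "NUTS2", "NUTS2"],
    })


def make_grid(values, cell_size=1000.0, x0=0.0, y0=None, nodata=-9999.0,
              units="ha"):
    values = np.asarray(values, dtype=float)
    if y0 is None:
        y0 = values.shape[0] * cell_size
    geom = GridGeometry(x0, y0, cell_size, *values.shape)
    return Grid(values, geom, nodata, units)


@pytest.fixture
def grid_factory():
    return make_grid
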