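import numpy as np
import pytest

from habshift.grid_model import Grid, GridStack
from habshift.synthetic_landscape import (
    ScenarioSpec,
    default_truth,
    make_landscape,
    true_suitability,
)


@pytest.fixture(scope="session")
def small_landscape():
    """A 60×60 landscape shared by read-only tests."""
    return make_landscape(ScenarioSpec(n_rows=60, n_cols=60, seed=7))


@pytest.fixture(scope="session")
def small_truth(small_landscape):
    return default_truth(small_landscape)


@pytest.fixture(scope="session")
def small_suitability(small_landscape, small_truth):
    return true_suitability(
        small_landscape.current, small_truth, elevation=small_landscape.elevation
    )


def grid_from(values, cell_size_km=1.0, origin=None, nodata=None, name="layer"):
    """Build a Grid from a nested list; nodata marks masked cells."""
    vals = np.asarray(values, dtype=float)
    mask = np.zeros(vals.shape, dtype=bool) if nodata is None else np.asarray(nodata, dtype=bool)
    if origin is None:
        origin = (0.0, vals.shape[0] * cell_size_km)
    return Grid(
        values=vals,
        nodata_mask=mask,
        cell_size_km=cell_size_km,
        origin_xy=origin,
        layer_name=name,
    )


def stack_from(named_values, cell_size_km=1.0):
    return GridStack(
        {n: grid_from(v, cell_size_km=cell_size_km, name=n) for n, v in named_values.items()}
    )
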