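import numpy as np
import pytest

from snakemaps.grid import Grid, GridSpec


@pytest.fixture
def spec():
    return GridSpec(origin_lon=10.0, origin_lat=1.0, n_rows=20, n_cols=25)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_grid(spec, rng):
    return Grid(spec, rng.uniform(0, 1, spec.shape))


def make_grid(values, origin_lon=0.0, origin_lat=None, cell_size=0.01):
    values = np.asarray(values, dtype=float)
    if origin_lat is None:
        origin_lat = values.shape[0] * cell_size
    spec = GridSpec(origin_lon, origin_lat, values.shape[0], values.shape[1], cell_size)
    return Grid(spec, values)
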