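import numpy as np
import pandas as pd
import pytest

from plumascape import GeoGrid, GridStack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    """2x2 grid, origin (0, 2), 1-degree cells: values [[1,2],[3,4]]."""
    return GeoGrid(np.array([[1.0, 2.0], [3.0, 4.0]]), 0.0, 2.0, 1.0, 1.0)


def make_samples(lons, lats, d2h, species=None):
    n = len(lons)
    table = pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(n)],
            "lon": lons,
            "lat": lats,
            "d2h_f": d2h,
        }
    )
    if species is not None:
        table["species"] = species
    return table


@pytest.fixture
def make_samples_fn():
    return make_samples


@pytest.fixture(scope="session")
def optimism_runs():
    """Holdout-vs-CV comparisons on the museum-like preset, three seeds,
    clustered and spatially uniform site placements (shared across tests
    because each run fits ~70 forests)."""
    from plumascape import experiments as ex

    return {
        "clustered": [ex.holdout_vs_cv(seed=s, clustered=True) for s in range(3)],
        "uniform": [ex.holdout_vs_cv(seed=s, clustered=False) for s in range(3)],
    }
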