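import numpy as np
import pandas as pd
import pytest

from cwr_phylospace.occurrences import GridDomain
from cwr_phylospace.phylotree import parse_newick
from cwr_phylospace.synthetic_data import SyntheticConfig, generate

FOUR_TIP_NEWICK = "((A:1,B:1):2,(C:3,D:1):1);"


@pytest.fixture
def four_tip_tree():
    return parse_newick(FOUR_TIP_NEWICK)


@pytest.fixture
def small_grid():
    return GridDomain(origin_lon=-75.0, origin_lat=0.0, cell_size=0.1, n_cols=10, n_rows=10)


@pytest.fixture(scope="session")
def small_config():
    """Compact synthetic scenario shared across tests needing a full bundle."""
    return SyntheticConfig(
        seed=42,
        n_species=20,
        grid=(15, 15, 0.1, -75.0, 0.0),
        n_records_total=600,
        n_departments=4,
        n_ecoregions=5,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate(small_config)


def random_records(rng: np.random.Generator, grid: GridDomain, n: int, species=("A", "B", "C")) -> pd.DataFrame:
    lon = grid.origin_lon + rng.random(n) * grid.n_cols * grid.cell_size
    lat = grid.origin_lat + rng.random(n) * grid.n_rows * grid.cell_size
    return pd.DataFrame(
        {
            "species": rng.choice(species, size=n),
            "lon": lon,
            "lat": lat,
            "type": rng.choice(["H", "G"], size=n),
            "source": "test",
        }
    )
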