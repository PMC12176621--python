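import numpy as np
import pandas as pd
import pytest

from benthicsplit import BathymetryGrid


@pytest.fixture()
def tiny_grid() -> BathymetryGrid:
    """3x4 grid: one land column (east), depths 100..2500 m elsewhere."""
    elevation = np.array(
        [
            [-100.0, -500.0, -1000.0, 120.0],
            [-250.0, -1000.0, -2500.0, 0.0],
            [-100.0, -750.0, -2000.0, 80.0],
        ]
    )
    return BathymetryGrid(
        lon_edges=np.array([0.0, 1.0, 2.0, 3.0, 4.0]),
        lat_edges=np.array([0.0, 1.0, 2.0, 3.0]),
        elevation_m=elevation,
    )


def make_records(
    lats, lons, depths, phyla=None, seabed=None, ids=None
) -> pd.DataFrame:
    n = len(lats)
    df = pd.DataFrame(
        {
            "record_id": ids if ids is not None else [f"t{i}" for i in range(n)],
            "latitude": np.asarray(lats, dtype=float),
            "longitude": np.asarray(lons, dtype=float),
            "record_depth_m": np.asarray(depths, dtype=float),
            "phylum": phyla if phyla is not None else ["Chordata"] * n,
            "kingdom": "Animalia",
            "scientific_name": pd.NA,
        }
    )
    if seabed is not None:
        df["seabed_depth_m"] = np.asarray(seabed, dtype=float)
    return df


@pytest.fixture(scope="session")
def default_grid():
    from benthicsplit import make_bathymetry

    return make_bathymetry(seed=7)


@pytest.fixture(scope="session")
def default_dataset(default_grid):
    """A mid-sized synthetic study used by several integration tests."""
    from benthicsplit import GeneratorConfig, simulate_records

    cfg = GeneratorConfig(seed=11, n_records=20_000)
    records, info = simulate_records(cfg, default_grid)
    return cfg, records, info
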