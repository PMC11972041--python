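import numpy as np
import pandas as pd
import pytest

from fragmon.config import RunConfig
from fragmon.geometry import TrackerGeometry


@pytest.fixture(scope="session")
def geom() -> TrackerGeometry:
    return TrackerGeometry()


@pytest.fixture()
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_hits(rows, layer="front"):
    """Build a pixel-hit table from (col, row, toa_ns, energy_kev) tuples."""
    return pd.DataFrame(
        {
            "layer": layer,
            "chip": 0,
            "col": [r[0] for r in rows],
            "row": [r[1] for r in rows],
            "toa_ns": [float(r[2]) for r in rows],
            "energy_kev": [float(r[3]) for r in rows],
        }
    )


def make_clusters(times, layer="front"):
    """Minimal cluster table with given timestamps (centroid at layer center)."""
    return pd.DataFrame(
        {
            "cluster_id": np.arange(len(times)),
            "layer": layer,
            "t_ns": np.asarray(times, dtype=float),
            "energy_kev": 40.0,
            "centroid_col": 254.0,
            "centroid_row": 126.5,
            "n_pixels": 1,
        }
    )
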