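"""Shared fixtures: toy tables and seeded synthetic studies.

All synthetic fixtures are generated at test time from the package's own
generator; the packaged example seed (3) is used wherever a test needs the
default study conditions.
"""

import numpy as np
import pandas as pd
import pytest

from diasal.datasets import CommunityTable, EnvironmentTable
from diasal.simulate import SimulationConfig, simulate_study

#: the packaged example seed used for the default synthetic study
STUDY_SEED = 3


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic study at the packaged example seed."""
    return simulate_study(SimulationConfig(), seed=STUDY_SEED)


@pytest.fixture(scope="session")
def small_study():
    """A reduced study for cheap structural tests."""
    cfg = SimulationConfig(n_locations=8, n_validation_sites=15, n_taxa=20)
    return simulate_study(cfg, seed=STUDY_SEED)


@pytest.fixture()
def toy_community():
    """3 sites x 2 taxa counts with season/location metadata."""
    data = pd.DataFrame({"A": [2.0, 400.0, 1.0], "B": [2.0, 0.0, 3.0]},
                        index=pd.Index(["S1", "S2", "S3"], name="site_id"))
    return CommunityTable(data, unit="counts",
                          season=pd.Series(["spring", "summer", "autumn"],
                                           index=data.index),
                          location=pd.Series(["L1", "L1", "L2"], index=data.index))


@pytest.fixture()
def toy_environment():
    data = pd.DataFrame({"Cl": [1000.0, 250.0, 8000.0],
                         "pH": [8.0, 7.5, 8.4]},
                        index=pd.Index(["S1", "S2", "S3"], name="site_id"))
    return EnvironmentTable(data, units={"Cl": "mg/l"})


def write_study_csvs(tmp_path, community: pd.DataFrame, environment: pd.DataFrame,
                     season=None, location=None):
    """Write toy CSVs in the exchange format and return their paths."""
    com = community.copy()
    if location is not None:
        com.insert(0, "location_id", location)
    if season is not None:
        com.insert(0, "season", season)
    com_path = tmp_path / "community.csv"
    env_path = tmp_path / "environment.csv"
    com.rename_axis("site_id").to_csv(com_path)
    environment.rename_axis("site_id").to_csv(env_path)
    return com_path, env_path
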