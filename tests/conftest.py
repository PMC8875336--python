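import numpy as np
import pytest

import grazemap as gm


@pytest.fixture(scope="session")
def sim_config():
    return gm.SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def sim_day(sim_config):
    """One full simulated collar day (361 fixes) plus its ground truth."""
    traj, truth = gm.simulate_trajectory(sim_config, animal_weight=50.0, day_index=0)
    return traj, truth


@pytest.fixture(scope="session")
def small_raster():
    """5x4 raster with distinct values, 10 m cells, NW origin at (0, 50)."""
    vals = np.arange(20, dtype=float).reshape(5, 4)
    return gm.Raster(vals, origin=(0.0, 50.0), cell_size=10.0, band_meaning="dem")


@pytest.fixture(scope="session")
def toy_grid():
    """Small 13-m analysis grid used by allocation tests."""
    return gm.GridSpec(origin=(0.0, 130.0), extent=(130.0, 130.0), cell_size=13.0)
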