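import numpy as np
import pytest

from strack.masks import LabeledMask, extract_regions
from strack.simulate import ColonyParams, simulate_colony
from strack.tracking import TrackingConfig, track_series


def make_mask(grid, frame_index=0):
    return LabeledMask(frame_index=frame_index, grid=np.asarray(grid, dtype=np.int32))


@pytest.fixture(scope="session")
def default_config():
    return TrackingConfig()


@pytest.fixture(scope="session")
def colony_seed1():
    """One simulated colony under the default study conditions."""
    return simulate_colony(ColonyParams(seed=1))


@pytest.fixture(scope="session")
def tracked_seed1(colony_seed1, default_config):
    return track_series(colony_seed1.masks, default_config)


@pytest.fixture
def static_masks():
    """Three identical frames: two separated rods, no movement or division."""
    grid = np.zeros((40, 40), dtype=np.int32)
    grid[5:8, 5:20] = 1
    grid[25:28, 10:30] = 2
    return [LabeledMask(frame_index=t, grid=grid.copy()) for t in range(3)]


def regions_of(grid, frame_index=0):
    return extract_regions(make_mask(grid, frame_index), warn_disconnected=False)
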