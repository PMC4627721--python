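import numpy as np
import pytest

from dichoptic.grid import NeuronGrid
from dichoptic.synthetic import (
    FS_GROUP_PARAMS,
    StudyDesign,
    default_contrasts,
    generate_trials,
)

ALL_CONDITIONS = ("none", "small", "medium", "large", "split")


@pytest.fixture(scope="session")
def coarse_grid():
    """Coarser analysis grid used for fitting-heavy tests."""
    return NeuronGrid(dx=0.5, dtheta=3.0)


@pytest.fixture(scope="session")
def tiny_grid():
    """21 x 18 grid small enough for double-loop convolution oracles."""
    return NeuronGrid(x_min=-5.0, x_max=5.0, dx=0.5, dtheta=10.0)


@pytest.fixture(scope="session")
def contrasts():
    return default_contrasts()


@pytest.fixture(scope="session")
def group_design():
    """Four homogeneous observers at the reference group parameters."""
    return StudyDesign(
        observers={f"O{i}": FS_GROUP_PARAMS for i in range(1, 5)},
        trials_per_cell=50,
    )


@pytest.fixture(scope="session")
def group_trials(group_design, coarse_grid):
    return generate_trials(group_design, "fs", seed=7, grid=coarse_grid)


@pytest.fixture(scope="session")
def single_observer_trials(coarse_grid):
    design = StudyDesign(observers={"O1": FS_GROUP_PARAMS}, trials_per_cell=50)
    return generate_trials(design, "fs", seed=1, grid=coarse_grid)
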