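import numpy as np
import pytest

from dexdrop import (
    GridSpec,
    InteractionSchedule,
    SolverConfig,
    ThermoParams,
    run_simulation,
)


@pytest.fixture(scope="session")
def thermo() -> ThermoParams:
    return ThermoParams()


@pytest.fixture(scope="session")
def schedule(thermo) -> InteractionSchedule:
    return InteractionSchedule(thermo)


@pytest.fixture(scope="session")
def grid() -> GridSpec:
    return GridSpec()


@pytest.fixture(scope="session")
def study_trajectory(grid, schedule):
    """The full study-parameter run (2600 macro steps, seed 1).

    Session-scoped because it takes tens of seconds; several acceptance
    checks (droplet array, conservation, confinement) share it.
    """
    cfg = SolverConfig(seed=1, snapshot_steps=(920, 1100, 1700, 2600))
    return run_simulation(grid, cfg, schedule)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
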