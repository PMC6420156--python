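import numpy as np
import pytest

from swarmtda import (
    ArenaConfig,
    ModelParams,
    TrajectorySet,
    generate_initial_conditions,
    simulate,
)


@pytest.fixture(scope="session")
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def control_params() -> ModelParams:
    return ModelParams().as_control()


@pytest.fixture(scope="session")
def arena() -> ArenaConfig:
    return ArenaConfig()


@pytest.fixture(scope="session")
def short_run(params) -> TrajectorySet:
    """A short interactive-model run reused by read-only tests."""
    ic = generate_initial_conditions(10, "clustered", seed=11)
    return simulate(ic, params, 80, seed=12)


def make_trajectory(positions, states=None, present=None, arena=None, **kw) -> TrajectorySet:
    """Build a TrajectorySet from a (T, N, 2) position array with defaults."""
    positions = np.asarray(positions, dtype=float)
    T, N = positions.shape[:2]
    if states is None:
        states = np.zeros((T, N), dtype=bool)
    if present is None:
        present = np.ones((T, N), dtype=bool)
    return TrajectorySet(
        positions=positions,
        states=np.asarray(states, bool),
        headings=np.zeros((T, N)),
        present=np.asarray(present, bool),
        arena=arena or ArenaConfig(),
        **kw,
    )
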