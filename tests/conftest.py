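import logging

import numpy as np
import pytest

from fluctlearn import (OUParams, EpochSchedule, LearningParams,
                        make_regulator_geometry, simulate_demand)


@pytest.fixture(autouse=True)
def _quiet_production_floor_logs():
    logger = logging.getLogger("fluctlearn.circuits")
    old = logger.level
    logger.setLevel(logging.ERROR)
    yield
    logger.setLevel(old)


@pytest.fixture
def params():
    return LearningParams()


@pytest.fixture
def geom_pair():
    """1D activator/repressor pair."""
    return make_regulator_geometry(2, nx=1)


@pytest.fixture
def env_1d():
    return OUParams(dbar=np.ones(1), M=np.array([[1.0]]), gamma=0.05, dt=1e-2)


@pytest.fixture
def demand_1d(env_1d):
    return simulate_demand(EpochSchedule.single(env_1d, 200.0), seed=42)


def constant_demand(value, nx=1, duration=200.0, dt=1e-2):
    """Zero-noise demand trajectory pinned at a constant vector."""
    env = OUParams(dbar=np.full(nx, float(value)) if np.isscalar(value)
                   else np.asarray(value, dtype=float),
                   M=np.eye(nx), gamma=0.0, dt=dt)
    return simulate_demand(EpochSchedule.single(env, duration), seed=0)
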