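import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rbcpop import defaults
from rbcpop.cohort import ReticSpec, StudySchedule, make_subject, simulate_subject
from rbcpop.grid import Grid
from rbcpop.solver import steady_state_from_birth

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ctx():
    return defaults.default_ctx()


@pytest.fixture(scope="session")
def params():
    return defaults.default_params()


@pytest.fixture(scope="session")
def grid(ctx):
    return defaults.sim_grid(ctx)


@pytest.fixture(scope="session")
def retic_spec():
    return ReticSpec(defaults.RETIC_MEAN_V, defaults.RETIC_MEAN_H,
                     defaults.RETIC_SD_V, defaults.RETIC_SD_H, defaults.RETIC_CORR)


@pytest.fixture(scope="session")
def birth(retic_spec, grid):
    return retic_spec.density_on(grid)


@pytest.fixture(scope="session")
def steady(params, birth, ctx):
    """Baseline steady state via the lifespan-truncated integration protocol."""
    return steady_state_from_birth(params, birth, ctx, birth_rate=defaults.BIRTH_RATE)


@pytest.fixture(scope="session")
def default_subject_series():
    """One no-jitter subject simulated through the full study schedule."""
    truth = make_subject(0, overrides={"jitter": 0.0})
    series = simulate_subject(truth, StudySchedule(), seed=1)
    return truth, series


@pytest.fixture(scope="session")
def baseline_draw(default_subject_series):
    _, series = default_subject_series
    return series.records[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
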