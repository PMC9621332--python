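import numpy as np
import pytest

from temporev import (
    AgentConfig,
    Preferences,
    build_schedule,
    freeze_outcomes,
    make_condition_pair,
    run_agent,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def std_prefs():
    """The simulation-standard preference vector P_o = (0.1, 0.6, 0.15, 0.15)."""
    return Preferences(0.1, 0.6, 0.3)


@pytest.fixture(scope="session")
def condition_pair():
    """A small discriminatively selected schedule pair (both conditions)."""
    return make_condition_pair(seed=7, n_candidates=3)


@pytest.fixture(scope="session")
def short_schedule():
    """A deterministic 500-trial schedule (intervals of 20) with frozen outcomes."""
    sched = build_schedule(
        np.full(25, 20), None, condition="regular", switch_at=500
    )
    table = freeze_outcomes(sched, seed=5)
    return sched, table


@pytest.fixture(scope="session")
def short_run(short_schedule, std_prefs):
    """One simulated agent on the short schedule, beliefs tracked."""
    sched, table = short_schedule
    cfg = AgentConfig(nu_max=10, gamma=5.0, preferences=std_prefs)
    return run_agent(cfg, sched, table, seed=42, track_beliefs=True)
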