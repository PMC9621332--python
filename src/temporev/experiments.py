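"""Seeded in-silico experiments: nu_max sweeps, template learning, preference grids."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .beliefs import AgentConfig
from .measures import (
    performance_series,
    probing_series,
    rmse_from_marginals,
    summary_means,
)
from .policy import Preferences
from .simulate import run_agent
from .task import DEFAULT_MU, DEFAULT_NU_REGULAR, make_condition_pair

__all__ = [
    "default_preferences",
    "run_numax_sweep",
    "run_template_learning",
    "run_preference_grid",
]


def default_preferences() -> Preferences:
    """The simulation-standard preference vector P_o = (0.1, 0.6, 0.15, 0.15)."""
    return Preferences(0.1, 0.6, 0.3)


def run_numax_sweep(
    nu_max_values=(1, 5, 10),
    n_runs: int = 50,
    condition: str = "regular",
    seed: int = 0,
    gamma: float = 5.0,
    schedule_pair=None,
    n_schedule_candidates: int = 20,
) -> pd.DataFrame:
    """Mean performance/probing trajectories per nu_max with 95% CIs.

    Each nu_max is run ``n_runs`` times on the condition's frozen schedule
    with gamma and the standard preferences; rows are (nu_max, trial,
    performance_mean, performance_lo/hi, probing_mean, probing_lo/hi).
    """
    rng = np.random.default_rng(seed)
    if schedule_pair is None:
        schedule_pair = make_condition_pair(
            int(rng.integers(2**31)), n_candidates=n_schedule_candidates
        )
    sched, table = schedule_pair[condition]
    frames = []
    for nu_max in nu_max_values:
        cfg = AgentConfig(nu_max=nu_max, gamma=gamma, preferences=default_preferences())
        perf = np.empty((n_runs, sched.T))
        probe = np.empty((n_runs, sched.T))
        for j in range(n_runs):
            res = run_agent(cfg, sched, table, seed=int(rng.integers(2**31)))
            perf[j] = performance_series(res.records)
            probe[j] = probing_series(res.records)
        ci = 1.96 / np.sqrt(n_runs)
        frames.append(
            pd.DataFrame(
                {
                    "nu_max": nu_max,
                    "trial": np.arange(1, sched.T + 1),
                    "performance_mean": perf.mean(0),
                    "performance_lo": perf.mean(0) - ci * perf.std(0),
                    "performance_hi": perf.mean(0) + ci * perf.std(0),
                    "probing_mean": probe.mean(0),
                    "probing_lo": probe.mean(0) - ci * probe.std(0),
                    "probing_hi": probe.mean(0) + ci * probe.std(0),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def run_template_learning(
    condition: str = "regular",
    seed: int = 0,
    nu_max: int = 10,
    gamma: float = 5.0,
    schedule_pair=None,
    n_schedule_candidates: int = 20,
):
    """Single-agent per-trial template marginals q_t(mu) and q_t(nu).

    Returns (q_mu (T, 41), q_nu (T, 10), SimulationResult).
    """
    rng = np.random.default_rng(seed)
    if schedule_pair is None:
        schedule_pair = make_condition_pair(
            int(rng.integers(2**31)), n_candidates=n_schedule_candidates
        )
    sched, table = schedule_pair[condition]
    cfg = AgentConfig(nu_max=nu_max, gamma=gamma, preferences=default_preferences())
    res = run_agent(
        cfg, sched, table, seed=int(rng.integers(2**31)), track_beliefs=True
    )
    return res.q_mu, res.q_nu, res


def run_preference_grid(
    p_minus_grid=None,
    p_plus_grid=(0.5, 0.55, 0.6),
    n_runs: int = 50,
    seed: int = 0,
    conditions=("regular", "irregular"),
    nu_max: int = 10,
    gamma: float = 5.0,
    schedule_pair=None,
    n_schedule_candidates: int = 20,
) -> pd.DataFrame:
    """Averaged measures over a (p_minus, p_plus) preference grid.

    One row per (p_minus, p_plus, condition): performance/probing averaged
    over trials 400..800 and RMSE of the temporal posterior at trial 800,
    each averaged over ``n_runs`` seeded runs.
    """
    if p_minus_grid is None:
        p_minus_grid = np.round(np.arange(0.05, 0.2501, 0.01), 3)
    rng = np.random.default_rng(seed)
    if schedule_pair is None:
        schedule_pair = make_condition_pair(
            int(rng.integers(2**31)), n_candidates=n_schedule_candidates
        )
    rows = []
    for condition in conditions:
        sched, table = schedule_pair[condition]
        true_nu = DEFAULT_NU_REGULAR if condition == "regular" else 1
        for p_plus in p_plus_grid:
            for p_minus in p_minus_grid:
                prefs = Preferences(p_minus, p_plus, 1.0 - p_minus - p_plus)
                cfg = AgentConfig(nu_max=nu_max, gamma=gamma, preferences=prefs)
                perf, probe, r_mu, r_nu = [], [], [], []
                for _ in range(n_runs):
                    res = run_agent(
                        cfg, sched, table, seed=int(rng.integers(2**31)),
                        track_beliefs=True,
                    )
                    perf.append(summary_means(performance_series(res.records)))
                    probe.append(summary_means(probing_series(res.records)))
                    rm, rn = rmse_from_marginals(
                        res.q_mu[799], res.q_nu[799], DEFAULT_MU, true_nu
                    )
                    r_mu.append(rm)
                    r_nu.append(rn)
                rows.append(
                    {
                        "condition": condition,
                        "p_minus": p_minus,
                        "p_plus": p_plus,
                        "performance": float(np.mean(perf)),
                        "probing": float(np.mean(probe)),
                        "rmse_mu": float(np.mean(r_mu)),
                        "rmse_nu": float(np.mean(r_nu)),
                    }
                )
    return pd.DataFrame(rows)
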