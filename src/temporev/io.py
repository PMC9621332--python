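"""CSV / JSON import and export for schedules, trial tables, and summaries."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .task import OutcomeTable, ReversalSchedule

__all__ = [
    "schedule_to_csv",
    "schedule_from_csv",
    "trials_from_csv",
    "trials_to_csv",
    "belief_trajectory_frame",
    "posterior_summaries_to_json",
]


def schedule_to_csv(
    path, schedule: ReversalSchedule, outcomes: OutcomeTable
) -> None:
    """Write trial, state, outcome_left, outcome_explore, outcome_right."""
    df = schedule.to_frame().merge(outcomes.to_frame(), on="trial")
    df.to_csv(path, index=False)


def schedule_from_csv(path, condition: str = "regular"):
    df = pd.read_csv(path)
    states = df["state"].to_numpy(dtype=int)
    flips = np.flatnonzero(np.diff(states) != 0) + 2  # 1-based flip trials
    sched = ReversalSchedule(
        condition=condition, states=states, reversal_trials=flips
    )
    table = OutcomeTable(
        outcome_left=df["outcome_left"].to_numpy(),
        outcome_explore=df["outcome_explore"].to_numpy(),
        outcome_right=df["outcome_right"].to_numpy(),
    )
    return sched, table


def trials_to_csv(path, records: pd.DataFrame) -> None:
    """Write subject, condition, trial, choice, outcome (missing as empty)."""
    records.to_csv(path, index=False)


def trials_from_csv(path) -> pd.DataFrame:
    """Read a behavioral trial table; empty choice/outcome cells become NaN."""
    df = pd.read_csv(path)
    required = {"subject", "trial", "choice", "outcome"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    return df


def belief_trajectory_frame(result) -> pd.DataFrame:
    """Per-trial belief diagnostics from a tracked simulation run."""
    if result.q_mu is None:
        raise ValueError("run the simulation with track_beliefs=True")
    from .templates import MU_GRID, NU_GRID

    ent = -np.sum(
        np.where(result.q_mu > 0, result.q_mu * np.log(result.q_mu), 0.0), axis=1
    )
    return pd.DataFrame(
        {
            "trial": np.arange(1, result.q_mu.shape[0] + 1),
            "q_s1": result.q_s1,
            "entropy_q_mu": ent,
            "argmax_mu": MU_GRID[result.q_mu.argmax(axis=1)],
            "argmax_nu": NU_GRID[result.q_nu.argmax(axis=1)],
        }
    )


def posterior_summaries_to_json(path, posteriors) -> None:
    """Write per-subject posterior summaries (gamma, P_o, exceedance, class)."""
    Path(path).write_text(
        json.dumps([p.to_dict() for p in posteriors], indent=2)
    )
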