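"""Closed-loop agent simulation on frozen schedules and outcome tables."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .beliefs import (
    AgentConfig,
    BeliefState,
    init_beliefs,
    predict,
    template_marginals,
    update_dirichlet,
    update_state_beliefs,
)
from .policy import action_probabilities, expected_free_energy, sample_action
from .task import OutcomeTable, ReversalSchedule

__all__ = ["SimulationResult", "run_agent"]


@dataclass
class SimulationResult:
    """Trial records, per-trial diagnostics, and the final belief state."""

    records: pd.DataFrame  # subject, trial, choice, outcome, correct
    efe: pd.DataFrame  # trial, G_left, G_explore, G_right, chosen
    q_mu: np.ndarray  # (T, 41) per-trial marginal over mu
    q_nu: np.ndarray  # (T, 10) per-trial marginal over nu
    q_s1: np.ndarray  # (T,) posterior probability of s1 = 1
    final_belief: BeliefState


def run_agent(
    config: AgentConfig,
    schedule: ReversalSchedule,
    outcomes: OutcomeTable,
    seed: int | np.random.Generator,
    subject: str = "sim",
    track_beliefs: bool = False,
) -> SimulationResult:
    """Run one agent for the full schedule, sampling actions per trial.

    Each trial: predict beliefs forward, score the available actions by
    expected free energy, sample a choice with precision gamma, look the
    outcome up in the frozen table, then update state beliefs and Dirichlet
    counts.  Fully reproducible from (config, schedules, seed).
    """
    if schedule.T != outcomes.T:
        raise ValueError("schedule and outcome table lengths differ")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    T = schedule.T
    belief = init_beliefs(config)
    actions = config.actions
    choices = np.empty(T, dtype=int)
    outs = np.empty(T, dtype=int)
    correct = np.zeros(T, dtype=bool)
    G_full = np.full((T, 3), np.nan)
    q_s1 = np.empty(T)
    q_mu = np.empty((T, 41)) if track_beliefs else None
    q_nu = np.empty((T, 10)) if track_beliefs else None
    for t in range(1, T + 1):
        efe = expected_free_energy(belief, config.preferences, actions)
        probs = action_probabilities(efe, config.gamma)
        a = sample_action(probs, rng, actions)
        o = outcomes.outcome(t, a)
        belief, _ = update_state_beliefs(belief, a, o)
        belief.counts = update_dirichlet(belief, a, o)
        choices[t - 1] = a
        outs[t - 1] = o
        high_card = 1 if schedule.states[t - 1] == 1 else 3
        correct[t - 1] = a == high_card
        for act, g in zip(efe.actions, efe.G):
            G_full[t - 1, act - 1] = g
        q_s1[t - 1] = belief.state_marginal()[0]
        if track_beliefs:
            q_mu[t - 1], q_nu[t - 1] = template_marginals(belief)
        if t < T:
            belief = predict(belief)
    records = pd.DataFrame(
        {
            "subject": subject,
            "trial": np.arange(1, T + 1),
            "choice": choices,
            "outcome": outs,
            "correct": correct,
        }
    )
    efe_df = pd.DataFrame(
        {
            "trial": np.arange(1, T + 1),
            "G_left": G_full[:, 0],
            "G_explore": G_full[:, 1],
            "G_right": G_full[:, 2],
            "chosen": choices,
        }
    )
    return SimulationResult(
        records=records,
        efe=efe_df,
        q_mu=q_mu,
        q_nu=q_nu,
        q_s1=q_s1,
        final_belief=belief,
    )
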