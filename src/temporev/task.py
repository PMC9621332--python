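"""Reversal schedules, frozen outcome tables, and schedule selection.

Two study conditions share the same mean between-reversal interval
(E[d] = mu + 1 = 20 trials): *irregular* draws intervals from a geometric
distribution (nu = 1) and *regular* from a negative binomial (nu_gen = 10
by default).  Each condition runs 1000 trials; the first 800 follow the
condition's own interval law and the last 200 replicate the reversal
series of the opposite condition's first 200 trials, producing a
statistics switch at trial 800.

Outcome tables are generated once per condition and replayed identically
to every agent: per trial the correct card's gain is Bernoulli(p_H = 0.8),
the incorrect card's Bernoulli(p_L = 0.2) (independent draws), and the
explore cue deterministically names the correct card.

The deployed schedule for each condition is chosen from a batch of
candidates to maximise the performance gap between a probe agent holding
the condition-correct temporal representation and one holding the opposite
representation, which sharpens downstream model comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .templates import TemporalTemplate

__all__ = [
    "ReversalSchedule",
    "OutcomeTable",
    "sample_intervals",
    "build_schedule",
    "freeze_outcomes",
    "select_discriminative_schedule",
    "make_condition_pair",
]

CONDITIONS = ("regular", "irregular")
DEFAULT_MU = 19
DEFAULT_NU_REGULAR = 10
DEFAULT_P_H = 0.8
DEFAULT_P_L = 0.2


def _check_condition(condition: str) -> None:
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")


@dataclass
class ReversalSchedule:
    """Per-trial latent context and reversal moments for one condition.

    ``states`` holds s1 in {1, 2} (1 = left card correct) for trials
    1..T; ``reversal_trials`` are the 1-based trials at which s1 flips.
    """

    condition: str
    states: np.ndarray
    reversal_trials: np.ndarray
    switch_at: int | None = None

    def __post_init__(self) -> None:
        _check_condition(self.condition)
        self.states = np.asarray(self.states, dtype=int)
        self.reversal_trials = np.asarray(self.reversal_trials, dtype=int)

    @property
    def T(self) -> int:
        return self.states.size

    def reversal_pattern(self, first: int, last: int) -> np.ndarray:
        """Boolean per-trial flip indicator over 1-based trials [first, last]."""
        flags = np.zeros(self.T + 1, dtype=bool)
        flags[self.reversal_trials] = True
        return flags[first : last + 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"trial": np.arange(1, self.T + 1), "state": self.states}
        )


def sample_intervals(
    condition: str,
    n_trials: int,
    generator_params: TemporalTemplate,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw i.i.d. between-reversal intervals tiling at least ``n_trials``.

    The irregular condition must use a geometric law (nu = 1); the regular
    condition a genuinely regular one (nu > 1).  Intervals are shifted
    negative binomial: 1 + (failures before nu successes at rate delta).
    """
    _check_condition(condition)
    t = generator_params
    if condition == "irregular" and t.nu != 1:
        raise ValueError("irregular condition requires nu = 1 (geometric intervals)")
    if condition == "regular" and t.nu <= 1:
        raise ValueError("regular condition requires nu > 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: list[int] = []
    total = 0
    while total < n_trials:
        block = 1 + rng.negative_binomial(t.nu, t.delta, size=64)
        for d in block:
            out.append(int(d))
            total += int(d)
            if total >= n_trials:
                break
    return np.array(out)


def build_schedule(
    own: np.ndarray,
    other_first200: np.ndarray | None,
    condition: str = "regular",
    T: int = 1000,
    switch_at: int = 800,
    start_state: int = 1,
) -> ReversalSchedule:
    """Assemble a schedule: own intervals to ``switch_at``, then a copied tail.

    ``other_first200`` is the flip-indicator series of the opposite
    condition's trials 1..(T - switch_at); reversals in the tail replay it
    shifted to trials switch_at+1..T.  Pass None for a schedule of length
    ``switch_at`` with no tail (used during candidate screening).
    """
    own = np.asarray(own, dtype=int)
    if np.any(own < 1):
        raise ValueError("intervals must be >= 1")
    if other_first200 is None:
        T = switch_at
        tail_flips = np.zeros(0, dtype=bool)
    else:
        tail_flips = np.asarray(other_first200, dtype=bool)
        if tail_flips.size != T - switch_at:
            raise ValueError(
                f"tail pattern must cover {T - switch_at} trials, got {tail_flips.size}"
            )
    flips = np.zeros(T + 1, dtype=bool)
    pos = np.cumsum(own) + 1  # a segment of length d keeps s1 for trials [t, t+d)
    flips[pos[pos <= switch_at]] = True
    flips[switch_at + 1 :] = tail_flips
    states = np.empty(T, dtype=int)
    s = start_state
    for t in range(1, T + 1):
        if flips[t]:
            s = 3 - s
        states[t - 1] = s
    return ReversalSchedule(
        condition=condition,
        states=states,
        reversal_trials=np.flatnonzero(flips),
        switch_at=switch_at if other_first200 is not None else None,
    )


@dataclass
class OutcomeTable:
    """Frozen per-trial outcomes for every choice, replayed to all agents."""

    outcome_left: np.ndarray  # in {1 loss, 2 gain}
    outcome_explore: np.ndarray  # in {3 cue-left, 4 cue-right}
    outcome_right: np.ndarray  # in {1, 2}

    def __post_init__(self) -> None:
        for name in ("outcome_left", "outcome_explore", "outcome_right"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=int))
        self.outcome_left.setflags(write=False)
        self.outcome_explore.setflags(write=False)
        self.outcome_right.setflags(write=False)

    @property
    def T(self) -> int:
        return self.outcome_left.size

    def outcome(self, trial: int, choice: int) -> int:
        """Outcome code for a 1-based trial and choice (1 left, 2 explore, 3 right)."""
        col = {1: self.outcome_left, 2: self.outcome_explore, 3: self.outcome_right}
        return int(col[choice][trial - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(1, self.T + 1),
                "outcome_left": self.outcome_left,
                "outcome_explore": self.outcome_explore,
                "outcome_right": self.outcome_right,
            }
        )


def freeze_outcomes(
    schedule: ReversalSchedule,
    p_H: float = DEFAULT_P_H,
    p_L: float = DEFAULT_P_L,
    seed: int | np.random.Generator = 0,
) -> OutcomeTable:
    """Draw the outcome table once: card gains Bernoulli, cues deterministic."""
    if not (0 <= p_H <= 1 and 0 <= p_L <= 1):
        raise ValueError("p_H and p_L must be probabilities")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    left_correct = schedule.states == 1
    p_left = np.where(left_correct, p_H, p_L)
    p_right = np.where(left_correct, p_L, p_H)
    gain_left = rng.random(schedule.T) < p_left
    gain_right = rng.random(schedule.T) < p_right
    return OutcomeTable(
        outcome_left=np.where(gain_left, 2, 1),
        outcome_explore=np.where(left_correct, 3, 4),
        outcome_right=np.where(gain_right, 2, 1),
    )


def select_discriminative_schedule(
    n_candidates: int,
    condition: str,
    probe_agents,
    seed: int | np.random.Generator,
    T: int = 800,
    mu: int = DEFAULT_MU,
    nu_gen: int = DEFAULT_NU_REGULAR,
    p_H: float = DEFAULT_P_H,
    p_L: float = DEFAULT_P_L,
    return_gaps: bool = False,
):
    """Pick, from a seeded batch, the schedule that best separates probe agents.

    For each candidate (length ``T``, no tail) both probe agents — one with
    the condition-correct temporal representation, one with the opposite —
    are run on a frozen outcome table, and the candidate maximising
    (correct-agent performance - wrong-agent performance), averaged over
    trials 400..T, is returned.  Ties break toward the earlier candidate.
    """
    from .measures import performance_series, summary_means
    from .simulate import run_agent

    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    _check_condition(condition)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gen = TemporalTemplate(mu, nu_gen if condition == "regular" else 1)
    correct_agent, wrong_agent = probe_agents
    best, best_gap = None, -np.inf
    all_gaps: list[float] = []
    for _ in range(n_candidates):
        intervals = sample_intervals(condition, T, gen, rng)
        cand = build_schedule(intervals, None, condition=condition, switch_at=T)
        table = freeze_outcomes(cand, p_H, p_L, rng)
        parts = []
        for cfg, sign in ((correct_agent, 1.0), (wrong_agent, -1.0)):
            res = run_agent(cfg, cand, table, seed=rng.integers(2**31))
            perf = summary_means(
                performance_series(res.records), from_trial=400, to_trial=T
            )
            parts.append(sign * perf)
        gap = sum(parts)
        all_gaps.append(gap)
        if gap > best_gap:
            best, best_gap = cand, gap
    if return_gaps:
        return best, np.array(all_gaps)
    return best


def make_condition_pair(
    seed: int,
    n_candidates: int = 20,
    probe_agents=None,
    T: int = 1000,
    switch_at: int = 800,
    mu: int = DEFAULT_MU,
    nu_gen: int = DEFAULT_NU_REGULAR,
    p_H: float = DEFAULT_P_H,
    p_L: float = DEFAULT_P_L,
) -> dict[str, tuple[ReversalSchedule, OutcomeTable]]:
    """Build the deployed (schedule, outcome table) pair for both conditions.

    Each condition's first ``switch_at`` trials come from its
    discriminatively selected base schedule; the tail replays the other
    condition's first ``T - switch_at`` trials' reversal series.  Returns
    ``{"regular": (schedule, outcomes), "irregular": (schedule, outcomes)}``.
    """
    from .beliefs import AgentConfig

    rng = np.random.default_rng(seed)
    tail_len = T - switch_at
    bases: dict[str, ReversalSchedule] = {}
    for condition in CONDITIONS:
        if probe_agents is None:
            correct = AgentConfig(nu_max=10 if condition == "regular" else 1)
            wrong = AgentConfig(nu_max=1 if condition == "regular" else 10)
            probes = (correct, wrong)
        else:
            probes = probe_agents
        bases[condition] = select_discriminative_schedule(
            n_candidates, condition, probes, rng, T=switch_at,
            mu=mu, nu_gen=nu_gen, p_H=p_H, p_L=p_L,
        )
    out: dict[str, tuple[ReversalSchedule, OutcomeTable]] = {}
    for condition in CONDITIONS:
        other = "irregular" if condition == "regular" else "regular"
        tail = bases[other].reversal_pattern(1, tail_len)
        base = bases[condition]
        # rebuild from the base's realised flips plus the copied tail
        flips = np.zeros(T + 1, dtype=bool)
        flips[base.reversal_trials] = True
        flips[switch_at + 1 :] = tail
        states = np.empty(T, dtype=int)
        s = 1
        for t in range(1, T + 1):
            if flips[t]:
                s = 3 - s
            states[t - 1] = s
        sched = ReversalSchedule(
            condition=condition,
            states=states,
            reversal_trials=np.flatnonzero(flips),
            switch_at=switch_at,
        )
        out[condition] = (sched, freeze_outcomes(sched, p_H, p_L, rng))
    return out
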