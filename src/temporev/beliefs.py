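"""Belief updating for the hidden semi-Markov reversal-learning agent.

The agent factorises the task into: a binary context ``s1`` (which card
currently carries the high reward probability), a latent phase ``f`` that
gates reversals (context flips deterministically exactly when the end phase
is occupied), a temporal template ``m = (mu, nu)`` governing phase dynamics,
and Dirichlet-distributed outcome contingencies ``rho[s1, s2]`` learned from
feedback.

Beliefs are carried as a joint array ``q[m, s1, f]`` over all 410 grid
templates (phases zero-padded to the widest template), plus a Dirichlet
count table ``alpha[s1, s2, o]``.  The per-trial cycle is

    predict -> (choose, observe) -> update_state_beliefs -> update_dirichlet

where predict propagates the joint through each template's phase kernel,
the state update is exact Bayes with the count-mean likelihood
``mu[s1, s2, o] = alpha / sum(alpha)``, and the count update adds the
posterior context probability to the (chosen action, observed outcome) cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .policy import Preferences
from .templates import MU_GRID, NU_GRID, TemplateGrid, segment_start_dist, template_prior

__all__ = [
    "DirichletCounts",
    "AgentConfig",
    "BeliefState",
    "default_alpha0",
    "init_beliefs",
    "predict",
    "update_state_beliefs",
    "update_dirichlet",
    "template_marginals",
]

# outcome codes (1-based, as in trial tables): 1 loss, 2 gain, 3 cue-left, 4 cue-right
LOSS, GAIN, CUE_LEFT, CUE_RIGHT = 1, 2, 3, 4
# choice codes: 1 left card, 2 explore, 3 right card
LEFT, EXPLORE, RIGHT = 1, 2, 3


def default_alpha0(n_options: int = 3) -> np.ndarray:
    """Prior Dirichlet counts ``alpha0[s1, s2, o]`` (0-based axes).

    Card choices carry moderately confident reward expectations formed in
    training: the correct pairing gets (loss 6, gain 32, cues 1, 1) so the
    prior mean gain probability is 32/40 = 0.8; the incorrect pairing the
    mirror (32, 6, 1, 1).  The explore arm is known to yield only the
    state-consistent cue: count 2 there, 0.01 on the other three outcomes.
    """
    a = np.empty((2, 3, 4))
    correct = np.array([6.0, 32.0, 1.0, 1.0])
    incorrect = np.array([32.0, 6.0, 1.0, 1.0])
    cue_l = np.array([0.01, 0.01, 2.0, 0.01])
    cue_r = np.array([0.01, 0.01, 0.01, 2.0])
    # s1 = 0: left card correct
    a[0, 0], a[0, 1], a[0, 2] = correct, cue_l, incorrect
    # s1 = 1: right card correct
    a[1, 0], a[1, 1], a[1, 2] = incorrect, cue_r, correct
    return a


@dataclass
class DirichletCounts:
    """Pseudo-counts ``alpha[s1, s2, o]`` over outcome contingencies."""

    table: np.ndarray  # (2, 3, 4), all entries > 0

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=float)
        if self.table.shape != (2, 3, 4):
            raise ValueError("alpha table must have shape (2, 3, 4)")
        if np.any(self.table <= 0):
            raise ValueError("alpha entries must be positive")

    def copy(self) -> "DirichletCounts":
        return DirichletCounts(self.table.copy())

    def outcome_probs(self) -> np.ndarray:
        """Posterior-mean outcome probabilities mu[s1, s2, o]."""
        return self.table / self.table.sum(axis=-1, keepdims=True)


@dataclass
class AgentConfig:
    """Free parameters of one agent: (nu_max, gamma, preferences, alpha0)."""

    nu_max: int = 10
    gamma: float = 5.0
    preferences: Preferences = field(
        default_factory=lambda: Preferences(0.1, 0.6, 0.3)
    )
    alpha0: np.ndarray | None = None
    n_options: int = 3
    init_phase: str = "segment_start"  # or "uniform"

    def __post_init__(self) -> None:
        if self.n_options not in (2, 3):
            raise ValueError("n_options must be 2 or 3")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.alpha0 is None:
            self.alpha0 = default_alpha0(self.n_options)

    @property
    def actions(self) -> tuple[int, ...]:
        """Available 1-based choice codes."""
        return (LEFT, RIGHT) if self.n_options == 2 else (LEFT, EXPLORE, RIGHT)


class _GridArrays:
    """Padded per-template arrays shared by all belief states on one grid."""

    def __init__(self, grid: TemplateGrid):
        self.grid = grid
        m = grid.n_templates
        self.n_phases_max = int(NU_GRID.max()) + 1  # 11
        self.delta = grid.deltas
        self.end = grid.nus.astype(int)  # 0-based end-phase index = nu
        self.pi = np.zeros((m, self.n_phases_max))
        for i, t in enumerate(grid.templates):
            self.pi[i, : t.n_phases] = segment_start_dist(t)
        ph = np.arange(self.n_phases_max)
        self.valid = ph[None, :] <= self.end[:, None]
        self.not_end = ph[None, :] < self.end[:, None]

    _cache: dict[int, "_GridArrays"] = {}

    @classmethod
    def for_nu_max(cls, nu_max: int) -> "_GridArrays":
        # grid geometry is identical for every nu_max; only weights differ
        if 0 not in cls._cache:
            cls._cache[0] = cls(template_prior(10))
        return cls._cache[0]


@dataclass
class BeliefState:
    """Joint beliefs q(m, s1, f) plus Dirichlet counts at one trial.

    ``is_predictive`` distinguishes the prior-for-this-trial beliefs
    (output of :func:`predict`) from the posterior after observing the
    trial's outcome (output of :func:`update_state_beliefs`).
    """

    config: AgentConfig
    joint: np.ndarray  # (410, 2, 11)
    counts: DirichletCounts
    trial: int = 0
    is_predictive: bool = False
    _arrays: _GridArrays = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self._arrays is None:
            self._arrays = _GridArrays.for_nu_max(self.config.nu_max)

    def check_normalized(self, atol: float = 1e-8) -> None:
        s = self.joint.sum()
        if not np.isclose(s, 1.0, atol=atol):
            raise ValueError(f"belief joint sums to {s}, expected 1")

    def template_marginal(self) -> np.ndarray:
        """q(m) over the 410-template grid."""
        return self.joint.sum(axis=(1, 2))

    def state_marginal(self) -> np.ndarray:
        """q(s1) (or predictive p~(s1))."""
        return self.joint.sum(axis=(0, 2))

    def copy(self) -> "BeliefState":
        return replace(self, joint=self.joint.copy(), counts=self.counts.copy())


def init_beliefs(config: AgentConfig) -> BeliefState:
    """Initial beliefs: template prior x uniform context x segment-start phases.

    Trial 1 is treated as if a reversal had just completed (phases drawn
    from each template's segment-start distribution); ``init_phase =
    "uniform"`` instead spreads phase mass evenly over each template's
    support.
    """
    arrays = _GridArrays.for_nu_max(config.nu_max)
    grid = template_prior(config.nu_max)
    if config.init_phase == "segment_start":
        phase = arrays.pi
    elif config.init_phase == "uniform":
        phase = arrays.valid / arrays.valid.sum(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown init_phase {config.init_phase!r}")
    joint = np.repeat(
        0.5 * grid.prior_weights[:, None, None] * phase[:, None, :], 2, axis=1
    )
    return BeliefState(
        config=config,
        joint=joint,
        counts=DirichletCounts(np.asarray(config.alpha0, dtype=float).copy()),
        trial=1,
        is_predictive=True,
        _arrays=arrays,
    )


def predict(belief: BeliefState) -> BeliefState:
    """One-step prediction of the joint (s1, f) through each phase kernel.

    Mass below the end phase stays (1 - delta) or advances (delta) with the
    context unchanged; mass on the end phase flips the context with
    certainty and re-initialises the phase from the segment-start
    distribution.  The template marginal is carried forward unchanged.
    Chaining predictions (no intervening update) is allowed: that is how
    missing-response trials propagate beliefs.
    """
    belief.check_normalized()
    a = belief._arrays
    q = belief.joint
    ne = q * a.not_end[:, None, :]
    end_q = q[np.arange(q.shape[0]), :, a.end]  # (410, 2)
    new = (1.0 - a.delta)[:, None, None] * ne
    new[:, :, 1:] += a.delta[:, None, None] * ne[:, :, :-1]
    new += a.pi[:, None, :] * end_q[:, ::-1][:, :, None]
    return replace(belief, joint=new, counts=belief.counts, is_predictive=True)


def _check_consistent(choice: int, outcome: int) -> None:
    if choice not in (LEFT, EXPLORE, RIGHT):
        raise ValueError(f"invalid choice {choice}")
    if outcome not in (LOSS, GAIN, CUE_LEFT, CUE_RIGHT):
        raise ValueError(f"invalid outcome {outcome}")
    if choice == EXPLORE and outcome not in (CUE_LEFT, CUE_RIGHT):
        raise ValueError("explore choices yield cue outcomes (3 or 4)")
    if choice != EXPLORE and outcome not in (LOSS, GAIN):
        raise ValueError("card choices yield loss/gain outcomes (1 or 2)")


def update_state_beliefs(
    belief: BeliefState, choice: int, outcome: int
) -> tuple[BeliefState, float]:
    """Exact Bayes update of q(m, s1, f) after observing one outcome.

    The Dirichlet-marginalised likelihood is the count mean
    ``mu[s1, a, o] = alpha[s1, a, o] / sum_i alpha[s1, a, i]``.  Returns the
    normalized posterior and the evidence (predictive outcome probability).
    """
    if not belief.is_predictive:
        raise ValueError("update expects a predictive belief state")
    belief.check_normalized()
    _check_consistent(choice, outcome)
    mu = belief.counts.outcome_probs()
    w = mu[:, choice - 1, outcome - 1]  # likelihood per s1, shape (2,)
    post = belief.joint * w[None, :, None]
    evidence = post.sum()
    if evidence <= 0:
        raise ValueError("zero evidence: outcome impossible under current counts")
    post /= evidence
    return (
        replace(belief, joint=post, counts=belief.counts, is_predictive=False),
        float(evidence),
    )


def update_dirichlet(belief: BeliefState, choice: int, outcome: int) -> DirichletCounts:
    """Add the posterior context probability to the chosen/observed cell.

    Only the column of the chosen action and row of the observed outcome
    move; the added mass is q(s1 = s) for each context s, so exactly one
    unit of count mass is added per trial.
    """
    if belief.is_predictive:
        raise ValueError("update_dirichlet expects the post-update posterior")
    _check_consistent(choice, outcome)
    q_s = belief.state_marginal()
    counts = belief.counts.copy()
    counts.table[:, choice - 1, outcome - 1] += q_s
    return counts


def template_marginals(belief: BeliefState) -> tuple[np.ndarray, np.ndarray]:
    """Marginal posteriors (q(mu) over the 41-grid, q(nu) over the 10-grid)."""
    q_m = belief.template_marginal()
    q_by = q_m.reshape(NU_GRID.size, MU_GRID.size)
    q_nu = q_by.sum(axis=1)
    q_mu = q_by.sum(axis=0)
    return q_mu, q_nu
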