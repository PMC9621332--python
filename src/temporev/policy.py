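"""Expected free energy and stochastic action selection.

One-step-ahead planning: for each available action the agent scores the
predicted outcome distribution against its prior preferences (risk, a KL
divergence) and adds the expected entropy of the outcome likelihood under
its Dirichlet beliefs (ambiguity).  Actions are sampled from a softmax of
the negative expected free energy with precision gamma, so high-gamma
agents approximately minimise G.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy.special import digamma, logsumexp

if TYPE_CHECKING:  # pragma: no cover
    from .beliefs import BeliefState

__all__ = [
    "Preferences",
    "EFEResult",
    "predictive_outcomes",
    "expected_free_energy",
    "action_probabilities",
    "sample_action",
]

_PREF_FLOOR = 1e-10  # keeps ln P_o finite when a preference entry is zero


@dataclass(frozen=True)
class Preferences:
    """Outcome preferences (p_minus, p_plus, p_c) for loss / gain / cues.

    The two informative cues share the cue preference equally, giving the
    expanded vector P_o = (p_minus, p_plus, p_c / 2, p_c / 2).  The ratio
    p_plus / p_c sets the balance between reward seeking and information
    seeking.
    """

    p_minus: float
    p_plus: float
    p_c: float

    def __post_init__(self) -> None:
        vals = (self.p_minus, self.p_plus, self.p_c)
        if any(v < 0 for v in vals):
            raise ValueError("preference entries must be nonnegative")
        if not np.isclose(sum(vals), 1.0, atol=1e-8):
            raise ValueError("preferences must sum to 1")
        if self.p_plus < self.p_minus:
            raise ValueError("gains must be preferred at least as much as losses")

    @property
    def vector(self) -> np.ndarray:
        """Expanded P_o over the four outcome codes."""
        return np.array(
            [self.p_minus, self.p_plus, self.p_c / 2.0, self.p_c / 2.0]
        )

    @property
    def log_vector(self) -> np.ndarray:
        return np.log(np.maximum(self.vector, _PREF_FLOOR))


@dataclass
class EFEResult:
    """Per-action expected free energy and its risk/ambiguity split (nats)."""

    actions: tuple[int, ...]  # 1-based choice codes
    G: np.ndarray
    risk: np.ndarray
    ambiguity: np.ndarray
    predictive: np.ndarray  # (n_actions, 4) marginal predictive outcome probs


def predictive_outcomes(belief: "BeliefState", action: int) -> np.ndarray:
    """Marginal predictive outcome distribution for one action.

    mu_bar[o] = sum_s1 p~(s1) alpha[s1, a, o] / sum_i alpha[s1, a, i]; the
    Dirichlet parameters are marginalised exactly (the mean survives the
    integral over rho).
    """
    s_marg = belief.state_marginal()
    mu = belief.counts.outcome_probs()
    return s_marg @ mu[:, action - 1, :]


def ambiguity_term(alpha: np.ndarray, s_marg: np.ndarray) -> np.ndarray:
    """Expected outcome entropy per action under Dirichlet beliefs.

    Uses E_Dir[x_i ln x_i] = mu_i (psi(alpha_i + 1) - psi(1 + sum_j alpha_j))
    so that ambiguity[a] = -sum_s1 p~(s1) sum_o mu[s1,a,o]
    (psi(alpha+1) - psi(1+sum)).  Always >= 0.
    """
    mu = alpha / alpha.sum(axis=-1, keepdims=True)
    inner = digamma(alpha + 1.0) - digamma(1.0 + alpha.sum(axis=-1, keepdims=True))
    per_state = (mu * inner).sum(axis=-1)  # (2, 3) = E[sum_o rho ln rho]
    return -(s_marg @ per_state)


def expected_free_energy(
    belief: "BeliefState",
    prefs: Preferences,
    actions: Sequence[int] | None = None,
) -> EFEResult:
    """Expected free energy G(a) = risk(a) + ambiguity(a) per action.

    risk(a) = KL(mu_bar(.|a) || P_o) penalises predicted outcomes that
    deviate from preferences; ambiguity(a) is the expected entropy of the
    outcome likelihood, which the informative explore arm keeps low.
    """
    if actions is None:
        actions = belief.config.actions
    actions = tuple(actions)
    s_marg = belief.state_marginal()
    mu = belief.counts.outcome_probs()
    cols = [a - 1 for a in actions]
    mu_bar = np.einsum("s,sao->ao", s_marg, mu[:, cols, :])  # (n_actions, 4)
    log_p = prefs.log_vector
    with np.errstate(divide="ignore", invalid="ignore"):
        risk = np.where(mu_bar > 0, mu_bar * (np.log(mu_bar) - log_p), 0.0).sum(axis=1)
    amb = ambiguity_term(belief.counts.table, s_marg)[cols]
    G = risk + amb
    if not np.all(np.isfinite(G)):
        raise FloatingPointError("non-finite expected free energy")
    return EFEResult(actions=actions, G=G, risk=risk, ambiguity=amb, predictive=mu_bar)


def action_probabilities(efe: EFEResult, gamma: float) -> np.ndarray:
    """Softmax choice probabilities p(a) ∝ exp(-gamma G(a)).

    gamma = 0 gives indifference; gamma >> 1 concentrates on argmin G.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    logits = -gamma * efe.G
    return np.exp(logits - logsumexp(logits))


def sample_action(
    probs: np.ndarray,
    rng: np.random.Generator | int,
    actions: Sequence[int] | None = None,
) -> int:
    """Categorical draw of a 1-based choice code."""
    if not np.isclose(probs.sum(), 1.0, atol=1e-8):
        raise ValueError("action probabilities must sum to 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if actions is None:
        actions = tuple(range(1, probs.size + 1))
    idx = rng.choice(probs.size, p=probs / probs.sum())
    return int(actions[idx])
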