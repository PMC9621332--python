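"""Temporal templates and discrete phase-type (DPH) duration distributions.

A temporal template ``m = (mu, nu)`` is a hypothesis about the statistics of
intervals between contingency reversals: ``mu`` sets the mean interval
(``E[d] = mu + 1`` trials) and ``nu`` its regularity.  The interval
distribution is a shifted negative binomial,

    p_m(d) = C(d + nu - 2, d - 1) (1 - delta)^(d-1) delta^nu,   d >= 1,

with phase-advance probability ``delta = nu / (mu + nu)``.  ``nu = 1``
collapses to a geometric distribution (the hidden-Markov, maximally
irregular limit); larger ``nu`` concentrates the distribution around its
mean (``Var[d] = mu + mu^2 / nu``).

Rather than tracking elapsed duration explicitly, the distribution is
realised as the first-passage time of a finite phase chain
``f in {1, .., nu + 1}``: each trial the phase advances with probability
``delta`` or stays put, and a reversal fires exactly when the end phase
``nu + 1`` is occupied, after which the phase re-initialises from the
segment-start distribution ``pi``.  Here ``pi`` is the Binomial(nu, delta)
pmf over ``f - 1``, the unique choice (verified against the first-passage
oracle) that makes the chain's inter-reversal intervals exactly negative
binomial on the support ``d >= 1``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from scipy.stats import binom

__all__ = [
    "MU_GRID",
    "NU_GRID",
    "TemporalTemplate",
    "PhaseKernel",
    "TemplateGrid",
    "duration_pmf",
    "phase_kernel",
    "segment_start_dist",
    "future_reversal_prob",
    "template_prior",
]

#: mean-interval grid spanned by the agent's hypothesis space (41 values)
MU_GRID = np.arange(5, 46)
#: regularity grid (nu = 1 is the HMM limit)
NU_GRID = np.arange(1, 11)


@dataclass(frozen=True)
class TemporalTemplate:
    """One hypothesis ``m = (mu, nu)`` about reversal statistics."""

    mu: int
    nu: int

    def __post_init__(self) -> None:
        if self.mu < 1:
            raise ValueError(f"mu must be >= 1, got {self.mu}")
        if not 1 <= self.nu <= 10:
            raise ValueError(f"nu must be in 1..10, got {self.nu}")

    @property
    def delta(self) -> float:
        """Per-trial phase-advance probability nu / (mu + nu)."""
        return self.nu / (self.mu + self.nu)

    @property
    def n_phases(self) -> int:
        return self.nu + 1

    @property
    def mean_duration(self) -> float:
        """Expected interval between reversals, mu + 1 trials."""
        return self.mu + 1.0

    @property
    def var_duration(self) -> float:
        return self.mu + self.mu**2 / self.nu

    def to_dict(self) -> dict:
        return {"mu": int(self.mu), "nu": int(self.nu), "delta": self.delta}


def duration_pmf(template: TemporalTemplate, d) -> np.ndarray | float:
    """Negative-binomial pmf of the between-reversal interval ``d >= 1``.

    Accepts a scalar or array of durations; computed in log space so that
    binomial coefficients stay finite for d up to several thousand.
    """
    d_arr = np.asarray(d)
    if np.any(d_arr < 1):
        raise ValueError("durations must be >= 1")
    nu, delta = template.nu, template.delta
    logp = (
        gammaln(d_arr + nu - 1)
        - gammaln(d_arr)
        - gammaln(nu)
        + (d_arr - 1) * np.log1p(-delta)
        + nu * np.log(delta)
    )
    out = np.exp(logp)
    return float(out) if np.isscalar(d) else out


def segment_start_dist(template: TemporalTemplate) -> np.ndarray:
    """Phase distribution ``pi`` right after a reversal.

    Binomial(nu, delta) over ``f - 1``; places ``delta**nu`` directly on the
    end phase so that back-to-back reversals (d = 1) carry the probability
    the negative binomial assigns them.
    """
    return binom.pmf(np.arange(template.n_phases), template.nu, template.delta)


@dataclass(frozen=True)
class PhaseKernel:
    """Row-stochastic phase transition matrix and segment-start distribution."""

    advance_stay: np.ndarray  # (nu+1, nu+1)
    init_dist: np.ndarray  # (nu+1,)

    def __post_init__(self) -> None:
        rows = self.advance_stay.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-12):
            raise ValueError("phase kernel rows must sum to 1")
        if not np.isclose(self.init_dist.sum(), 1.0, atol=1e-12):
            raise ValueError("init_dist must sum to 1")


def phase_kernel(template: TemporalTemplate) -> PhaseKernel:
    """Build the DPH transition kernel for a template.

    Rows ``f <= nu``: stay with probability ``1 - delta``, advance to
    ``f + 1`` with probability ``delta``.  Row ``nu + 1`` (end phase):
    re-initialise from the segment-start distribution.
    """
    n = template.n_phases
    delta = template.delta
    mat = np.zeros((n, n))
    idx = np.arange(n - 1)
    mat[idx, idx] = 1.0 - delta
    mat[idx, idx + 1] = delta
    mat[n - 1] = segment_start_dist(template)
    return PhaseKernel(advance_stay=mat, init_dist=mat[n - 1].copy())


def future_reversal_prob(template: TemporalTemplate, tau_max: int) -> np.ndarray:
    """Marginal probability that a reversal occurs tau trials after one.

    Conditioned on a reversal at trial t (end phase occupied at t - 1), the
    phase re-initialises and ``delta_m[tau] = P(f_{t+tau-1} = nu + 1)`` is
    obtained by propagating the phase chain.  Constant ``1 / (mu + 1)`` in
    the geometric (nu = 1) limit; oscillatory with period ~ mu + 1 for
    large nu.
    """
    if tau_max < 1:
        raise ValueError("tau_max must be >= 1")
    kern = phase_kernel(template)
    p = kern.init_dist.copy()
    out = np.empty(tau_max)
    for tau in range(tau_max):
        out[tau] = p[-1]
        p = p @ kern.advance_stay
    return out


@dataclass
class TemplateGrid:
    """The agent's full hypothesis space over (mu, nu) with prior weights.

    Templates are ordered nu-major: index ``(nu - 1) * 41 + (mu - 5)``.
    ``prior_weights`` follow the factorised prior: uniform over the 41-point
    mu grid times ``1/nu_max`` for ``nu <= nu_max`` (zero above).
    """

    nu_max: int
    mus: np.ndarray = field(repr=False)
    nus: np.ndarray = field(repr=False)
    prior_weights: np.ndarray = field(repr=False)

    @property
    def n_templates(self) -> int:
        return self.mus.size

    @property
    def templates(self) -> list[TemporalTemplate]:
        return [TemporalTemplate(int(m), int(n)) for m, n in zip(self.mus, self.nus)]

    @property
    def deltas(self) -> np.ndarray:
        return self.nus / (self.mus + self.nus)

    def to_json(self) -> str:
        recs = [
            {"mu": int(m), "nu": int(n), "delta": float(d), "weight": float(w)}
            for m, n, d, w in zip(self.mus, self.nus, self.deltas, self.prior_weights)
        ]
        return json.dumps({"nu_max": self.nu_max, "templates": recs})

    @classmethod
    def from_json(cls, text: str) -> "TemplateGrid":
        obj = json.loads(text)
        recs = obj["templates"]
        return cls(
            nu_max=int(obj["nu_max"]),
            mus=np.array([r["mu"] for r in recs]),
            nus=np.array([r["nu"] for r in recs]),
            prior_weights=np.array([r["weight"] for r in recs]),
        )


def template_prior(nu_max: int) -> TemplateGrid:
    """Factorised template prior p(mu, nu | nu_max) over the 41 x 10 grid.

    ``nu_max`` bounds the regularity the agent can represent a priori:
    ``nu_max = 1`` pins all mass on the geometric (HMM) templates.
    """
    if not 1 <= int(nu_max) <= 10:
        raise ValueError(f"nu_max must be in 1..10, got {nu_max}")
    nus = np.repeat(NU_GRID, MU_GRID.size)
    mus = np.tile(MU_GRID, NU_GRID.size)
    weights = np.where(nus <= nu_max, 1.0 / (MU_GRID.size * nu_max), 0.0)
    return TemplateGrid(nu_max=int(nu_max), mus=mus, nus=nus, prior_weights=weights)
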