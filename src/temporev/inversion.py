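"""Hierarchical Bayesian inversion of choice data.

Given a subject's full choice/outcome sequence, belief trajectories are
simulated once per candidate temporal prior ``nu_max`` in 1..10 (belief
updating involves neither the choice precision ``gamma`` nor the outcome
preferences ``P_o``), caching for every likelihood trial the predictive
outcome matrices and ambiguity terms from which the expected free energy —
and hence the softmax choice likelihood — can be reconstructed for any
``(gamma, P_o)`` in closed form.  The response likelihood uses trials
400..T only; the full sequence still drives belief updating.

The population model is a random-effects mixture: per condition a
Dirichlet weight vector ``r`` over the ten ``nu_max`` values, shrunk
toward uniform by a half-Cauchy scale ``tau`` (concentration ``1/tau``);
per subject an Inverse-Gamma(2, 2) choice precision and a flat Dirichlet
simplex mapped to preferences via ``P_o = (p1/2, p1/2 + p2, p3/2, p3/2)``
(which enforces gain preference >= loss preference).  ``nu_max`` is
marginalised out of the likelihood, and the posterior is sampled with a
collapsed Metropolis-within-Gibbs scheme: adaptive random-walk updates of
each subject's ``(log gamma, p)`` block against the marginalised
likelihood, exact categorical draws of the ``nu_max`` indicators, conjugate
Dirichlet draws of ``r``, and an adaptive random-walk update of
``log tau``.  Per posterior sample the responsibility
``p_s(nu_max = nu | data)`` is computed exactly, and subjects are
classified by the exceedance probability of the per-sample argmax,
binarised at ``nu_max = 1`` versus ``nu_max > 1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .beliefs import (
    AgentConfig,
    init_beliefs,
    predict,
    update_dirichlet,
    update_state_beliefs,
)
from .policy import Preferences, ambiguity_term
from .simulate import run_agent
from .templates import NU_GRID

__all__ = [
    "preference_transform",
    "LikelihoodCache",
    "build_likelihood_cache",
    "response_loglik",
    "SamplerSettings",
    "FitResult",
    "fit_hierarchical",
    "numax_posterior",
    "exceedance",
    "classify",
    "SubjectPosterior",
    "subject_posteriors",
    "confusion_experiment",
]

NU_VALUES = tuple(int(v) for v in NU_GRID)  # candidate nu_max values 1..10
LIK_FROM_TRIAL = 400  # first trial entering the response likelihood (1-based)


def preference_transform(p) -> Preferences:
    """Map a 3-simplex point to preferences P_o = (p1/2, p1/2 + p2, p3/2, p3/2).

    The construction guarantees p_plus - p_minus = p2 >= 0.
    """
    p = np.asarray(p, dtype=float)
    if p.shape != (3,) or np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("p must be a point on the 3-simplex")
    return Preferences(p_minus=p[0] / 2.0, p_plus=p[0] / 2.0 + p[1], p_c=p[2])


@dataclass
class LikelihoodCache:
    """Per-subject reconstruction kit for the choice likelihood.

    For each candidate ``nu_max`` (axis 0) and each likelihood trial (axis
    1), ``mu_bar`` holds the marginal predictive outcome matrix per
    available action and ``base = sum_o mu_bar ln mu_bar + ambiguity`` the
    preference-independent part of G, so that
    ``G = base - mu_bar @ ln P_o``.
    """

    subject: str
    condition: str
    actions: tuple[int, ...]  # available 1-based choice codes
    trials: np.ndarray  # 1-based trial indices in the likelihood
    choice_idx: np.ndarray  # index into actions; -1 for missing/excluded
    mu_bar: np.ndarray  # (10, nT, nA, 4)
    base: np.ndarray  # (10, nT, nA)

    @property
    def n_included(self) -> int:
        return int((self.choice_idx >= 0).sum())


def build_likelihood_cache(
    records: pd.DataFrame,
    subject: str | None = None,
    condition: str = "regular",
    alpha0: np.ndarray | None = None,
    n_options: int = 3,
    from_trial: int = LIK_FROM_TRIAL,
) -> LikelihoodCache:
    """Replay a subject's choices/outcomes under every candidate nu_max.

    The agent is conditioned on the observed sequence (no action sampling);
    missing responses propagate beliefs by prediction only and are flagged
    excluded from the likelihood.  Raises on a choice/outcome mismatch,
    naming the trial.
    """
    df = records.sort_values("trial").reset_index(drop=True)
    if subject is None:
        subject = str(df["subject"].iloc[0]) if "subject" in df else "subject"
    T = int(df["trial"].max())
    choices = np.full(T + 1, -1, dtype=int)
    outcomes = np.full(T + 1, -1, dtype=int)
    for t, c, o in zip(df["trial"], df["choice"], df["outcome"]):
        if pd.notna(c):
            choices[int(t)] = int(c)
            outcomes[int(t)] = int(o) if pd.notna(o) else -1
    actions = (1, 3) if n_options == 2 else (1, 2, 3)
    cols = [a - 1 for a in actions]
    trials = np.arange(from_trial, T + 1)
    n_t, n_a = trials.size, len(actions)
    mu_bar = np.empty((len(NU_VALUES), n_t, n_a, 4))
    base = np.empty((len(NU_VALUES), n_t, n_a))
    choice_idx = np.full(n_t, -1, dtype=int)
    act_to_idx = {a: i for i, a in enumerate(actions)}
    for k, nu_max in enumerate(NU_VALUES):
        cfg = AgentConfig(nu_max=nu_max, alpha0=alpha0, n_options=n_options)
        belief = init_beliefs(cfg)
        for t in range(1, T + 1):
            if t >= from_trial:
                i = t - from_trial
                s_marg = belief.state_marginal()
                mu = belief.counts.outcome_probs()
                mb = np.einsum("s,sao->ao", s_marg, mu[:, cols, :])
                with np.errstate(divide="ignore", invalid="ignore"):
                    ent = np.where(mb > 0, mb * np.log(mb), 0.0).sum(axis=-1)
                amb = ambiguity_term(belief.counts.table, s_marg)[cols]
                mu_bar[k, i] = mb
                base[k, i] = ent + amb
            a = choices[t]
            if a >= 0:
                o = outcomes[t]
                try:
                    belief, _ = update_state_beliefs(belief, a, o)
                except ValueError as err:
                    raise ValueError(f"trial {t}: {err}") from err
                belief.counts = update_dirichlet(belief, a, o)
                if k == 0 and t >= from_trial:
                    choice_idx[t - from_trial] = act_to_idx[a]
            if t < T:
                belief = predict(belief)
    return LikelihoodCache(
        subject=subject,
        condition=condition,
        actions=actions,
        trials=trials,
        choice_idx=choice_idx,
        mu_bar=mu_bar,
        base=base,
    )


def _loglik_all_nu(cache: LikelihoodCache, gamma: float, prefs: Preferences) -> np.ndarray:
    """Vector of response log-likelihoods, one per candidate nu_max."""
    logits = -gamma * (cache.base - cache.mu_bar @ prefs.log_vector)
    lse = logsumexp(logits, axis=2)
    ci = np.clip(cache.choice_idx, 0, None)
    pick = np.take_along_axis(logits, ci[None, :, None], axis=2)[..., 0]
    valid = cache.choice_idx >= 0
    return ((pick - lse) * valid).sum(axis=1)


def response_loglik(
    cache: LikelihoodCache, nu_max: int, gamma: float, prefs: Preferences
) -> float:
    """Log-likelihood of the subject's included choices under one nu_max."""
    if nu_max not in NU_VALUES:
        raise ValueError(f"nu_max must be in {NU_VALUES}")
    return float(_loglik_all_nu(cache, gamma, prefs)[nu_max - 1])


def numax_posterior(loglik_nu: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Responsibility p_s(nu_max = nu | data) for one posterior sample.

    Bayes rule in log space over the ten mixture components with weights
    ``r`` and per-component response log-likelihoods ``loglik_nu``.
    """
    logw = np.log(np.maximum(r, 1e-300)) + loglik_nu
    return np.exp(logw - logsumexp(logw))


def exceedance(resp_samples: np.ndarray) -> np.ndarray:
    """X_i = fraction of posterior samples in which nu = i has the largest
    responsibility (ties broken toward smaller nu)."""
    resp = np.atleast_2d(resp_samples)
    winners = resp.argmax(axis=1)
    return np.bincount(winners, minlength=resp.shape[1]) / resp.shape[0]


def classify(X: np.ndarray) -> str:
    """Binary class from exceedance probabilities: 'numax=1' or 'numax>1'."""
    return "numax>1" if int(np.argmax(X)) + 1 > 1 else "numax=1"


# --------------------------------------------------------------------------
# hierarchical sampler


@dataclass
class SamplerSettings:
    n_chains: int = 4
    n_warmup: int = 500
    n_samples: int = 500
    mh_steps: int = 2  # MH hits per subject block per sweep
    target_accept: float = 0.30
    rhat_threshold: float = 1.05


@dataclass
class FitResult:
    """Posterior samples (chains stacked) and diagnostics."""

    subjects: list[str]
    conditions: list[str]  # per subject
    condition_levels: list[str]
    tau: np.ndarray  # (S,)
    r: np.ndarray  # (S, n_cond, 10)
    gamma: np.ndarray  # (S, N)
    p: np.ndarray  # (S, N, 3)
    resp: np.ndarray  # (S, N, 10) per-sample nu_max responsibilities
    rhat: dict[str, float] = field(default_factory=dict)
    accept: dict[str, float] = field(default_factory=dict)
    n_chains: int = 1

    @property
    def n_samples(self) -> int:
        return self.tau.size


def _log_invgamma(gamma: float, a: float = 2.0, b: float = 2.0) -> float:
    return a * np.log(b) - gammaln(a) - (a + 1) * np.log(gamma) - b / gamma


def _softmax3(z: np.ndarray) -> np.ndarray:
    zz = np.array([z[0], z[1], 0.0])
    e = np.exp(zz - zz.max())
    return e / e.sum()


def _subject_logprior(log_gamma: float, p: np.ndarray) -> float:
    # InvGamma(2,2) on gamma with log-transform Jacobian; Dirichlet(1,1,1) on
    # p via the 2-df softmax transform whose Jacobian determinant is p1*p2*p3.
    gamma = np.exp(log_gamma)
    return _log_invgamma(gamma) + log_gamma + float(np.sum(np.log(p)))


def _log_tau_target(log_tau: float, r_all: np.ndarray) -> float:
    # half-Cauchy(0,1) on tau (log-transform Jacobian included) plus the
    # Dirichlet(ones/tau) density of each condition-level weight vector.
    tau = np.exp(log_tau)
    out = np.log(2.0 / np.pi) - np.log1p(tau**2) + log_tau
    c = 1.0 / tau
    k = r_all.shape[-1]
    for r in np.atleast_2d(r_all):
        out += gammaln(k * c) - k * gammaln(c) + (c - 1.0) * np.sum(np.log(r))
    return float(out)


class _AdaptiveScale:
    """Robbins-Monro step-size adaptation toward a target acceptance rate,
    with optional diagonal (per-coordinate) preconditioning from a running
    variance estimate of the warmup draws."""

    def __init__(self, scale: float, target: float, dim: int = 1):
        self.log_scale = np.log(scale)
        self.target = target
        self.n_acc = 0
        self.n_tot = 0
        self.dim = dim
        self._mean = np.zeros(dim)
        self._m2 = np.zeros((dim, dim)) if dim > 1 else np.zeros(dim)
        self._n = 0

    def update(self, accepted: bool, i: int, adapting: bool) -> None:
        self.n_tot += 1
        self.n_acc += accepted
        if adapting:
            step = 1.0 / np.sqrt(i + 10.0)
            self.log_scale += step * ((1.0 if accepted else 0.0) - self.target)

    def observe(self, x: np.ndarray) -> None:
        """Welford update of the sample covariance (warmup only)."""
        x = np.atleast_1d(x)
        self._n += 1
        delta = x - self._mean
        self._mean += delta / self._n
        self._m2 = self._m2 + np.outer(delta, x - self._mean) if self.dim > 1 else (
            self._m2 + delta * (x - self._mean)
        )

    @property
    def chol(self) -> np.ndarray:
        """Cholesky factor of the adapted proposal covariance."""
        if self._n < 50:
            return np.eye(self.dim)
        cov = self._m2 / max(self._n - 1, 1) + 1e-6 * np.eye(self.dim)
        return np.linalg.cholesky(cov)

    @property
    def scale(self) -> float:
        return float(np.exp(self.log_scale))

    @property
    def rate(self) -> float:
        return self.n_acc / max(self.n_tot, 1)


def fit_hierarchical(
    caches: list[LikelihoodCache],
    settings: SamplerSettings | None = None,
    seed: int = 0,
    prior_only: bool = False,
    fix_tau: float | None = None,
) -> FitResult:
    """Sample the marginalised hierarchical posterior for a set of subjects.

    ``prior_only`` disables the response likelihood (all component
    log-likelihoods set to zero), which is used for prior-recovery checks;
    ``fix_tau`` pins the shrinkage scale (its tiny-tau limit forces the
    condition weights to uniform 1/10).
    Convergence is reported via split R-hat on log tau and the subject
    precisions; values above the threshold trigger a warning, never a
    silent pass.
    """
    if settings is None:
        settings = SamplerSettings()
    n_sub = len(caches)
    if n_sub == 0:
        raise ValueError("need at least one subject cache")
    cond_levels = sorted({c.condition for c in caches})
    cond_idx = np.array([cond_levels.index(c.condition) for c in caches])
    n_cond = len(cond_levels)
    K = len(NU_VALUES)

    def loglik_nu(i: int, gamma: float, p: np.ndarray) -> np.ndarray:
        if prior_only:
            return np.zeros(K)
        return _loglik_all_nu(caches[i], gamma, preference_transform(p))

    chains: list[dict[str, np.ndarray]] = []
    accept_rates: dict[str, float] = {}
    master = np.random.default_rng(seed)
    for chain in range(settings.n_chains):
        rng = np.random.default_rng(master.integers(2**31))
        # --- init
        log_tau = (
            float(np.log(fix_tau)) if fix_tau is not None else float(rng.normal(0.0, 0.5))
        )
        # start the condition weights at the shrinkage point (uniform); a
        # random draw can seed a self-reinforcing assignment mode
        r = np.full((n_cond, K), 1.0 / K)
        z = rng.normal(0.0, 0.3, size=(n_sub, 3))  # (log gamma, z1, z2)
        z[:, 0] += np.log(2.0)
        p_cur = np.stack([_softmax3(z[i, 1:]) for i in range(n_sub)])
        ll_nu = np.stack(
            [loglik_nu(i, np.exp(z[i, 0]), p_cur[i]) for i in range(n_sub)]
        )
        sub_scales = [
            _AdaptiveScale(0.2, settings.target_accept, dim=3) for _ in range(n_sub)
        ]
        tau_scale = _AdaptiveScale(0.5, settings.target_accept)

        def mix_ll(i: int, ll: np.ndarray) -> float:
            return float(logsumexp(np.log(np.maximum(r[cond_idx[i]], 1e-300)) + ll))

        cur_lp = np.array(
            [
                _subject_logprior(z[i, 0], p_cur[i]) + mix_ll(i, ll_nu[i])
                for i in range(n_sub)
            ]
        )
        n_sweeps = settings.n_warmup + settings.n_samples
        keep = {
            "tau": np.empty(settings.n_samples),
            "r": np.empty((settings.n_samples, n_cond, K)),
            "gamma": np.empty((settings.n_samples, n_sub)),
            "p": np.empty((settings.n_samples, n_sub, 3)),
            "resp": np.empty((settings.n_samples, n_sub, K)),
        }
        for sweep in range(n_sweeps):
            adapting = sweep < settings.n_warmup
            # (1) subject blocks: MH against the nu-marginalised likelihood
            for i in range(n_sub):
                sc = sub_scales[i]
                for _ in range(settings.mh_steps):
                    prop = z[i] + sc.scale * (sc.chol @ rng.normal(size=3))
                    p_prop = _softmax3(prop[1:])
                    ll_prop = loglik_nu(i, np.exp(prop[0]), p_prop)
                    lp_prop = _subject_logprior(prop[0], p_prop) + mix_ll(i, ll_prop)
                    acc = np.log(rng.random()) < lp_prop - cur_lp[i]
                    if acc:
                        z[i], p_cur[i], ll_nu[i], cur_lp[i] = (
                            prop, p_prop, ll_prop, lp_prop,
                        )
                    sc.update(bool(acc), sweep, adapting)
                if adapting:
                    sc.observe(z[i])
            # (2) nu_max indicators from exact conditionals
            resp = np.empty((n_sub, K))
            nu_ind = np.empty(n_sub, dtype=int)
            for i in range(n_sub):
                resp[i] = numax_posterior(ll_nu[i], r[cond_idx[i]])
                nu_ind[i] = rng.choice(K, p=resp[i])
            # (3) conjugate Dirichlet draw of the condition weights
            tau = np.exp(log_tau)
            for c in range(n_cond):
                counts = np.bincount(nu_ind[cond_idx == c], minlength=K)
                r[c] = rng.dirichlet(np.ones(K) / tau + counts)
            # the r update changes each subject's mixture weight term
            cur_lp = np.array(
                [
                    _subject_logprior(z[i, 0], p_cur[i]) + mix_ll(i, ll_nu[i])
                    for i in range(n_sub)
                ]
            )
            # (4) shrinkage scale tau
            if fix_tau is None:
                prop_lt = log_tau + tau_scale.scale * rng.normal()
                acc = np.log(rng.random()) < _log_tau_target(
                    prop_lt, r
                ) - _log_tau_target(log_tau, r)
                if acc:
                    log_tau = prop_lt
                tau_scale.update(bool(acc), sweep, adapting)
            if not adapting:
                j = sweep - settings.n_warmup
                keep["tau"][j] = np.exp(log_tau)
                keep["r"][j] = r
                keep["gamma"][j] = np.exp(z[:, 0])
                keep["p"][j] = p_cur
                for i in range(n_sub):
                    keep["resp"][j, i] = numax_posterior(ll_nu[i], r[cond_idx[i]])
        chains.append(keep)
        accept_rates[f"chain{chain}_subjects"] = float(
            np.mean([s.rate for s in sub_scales])
        )
        accept_rates[f"chain{chain}_tau"] = tau_scale.rate

    # --- diagnostics on per-chain draws, then stack
    rhat = _split_rhat(chains, settings)
    result = FitResult(
        subjects=[c.subject for c in caches],
        conditions=[c.condition for c in caches],
        condition_levels=cond_levels,
        tau=np.concatenate([c["tau"] for c in chains]),
        r=np.concatenate([c["r"] for c in chains]),
        gamma=np.concatenate([c["gamma"] for c in chains]),
        p=np.concatenate([c["p"] for c in chains]),
        resp=np.concatenate([c["resp"] for c in chains]),
        rhat=rhat,
        accept=accept_rates,
        n_chains=settings.n_chains,
    )
    bad = {k: v for k, v in rhat.items() if v > settings.rhat_threshold}
    if bad:
        warnings.warn(f"split R-hat above {settings.rhat_threshold}: {bad}")
    return result


def _split_rhat(chains: list[dict[str, np.ndarray]], settings: SamplerSettings) -> dict:
    import arviz as az

    if len(chains) < 2:
        return {}
    log_tau = np.log(np.stack([c["tau"] for c in chains]))
    gamma = np.log(np.stack([c["gamma"] for c in chains]))
    out = {"log_tau": float(az.rhat(log_tau))}
    rh = az.rhat(az.convert_to_dataset(gamma))["x"].values
    for i, v in enumerate(np.atleast_1d(rh)):
        out[f"log_gamma_{i}"] = float(v)
    return out


# --------------------------------------------------------------------------
# per-subject summaries and the simulated confusion experiment


@dataclass
class SubjectPosterior:
    """Classification summary for one subject."""

    subject: str
    condition: str
    gamma_median: float
    p_o_median: np.ndarray  # (4,)
    X: np.ndarray  # exceedance over nu_max
    map_numax: int
    binary_class: str

    def to_dict(self) -> dict:
        return {
            "subject": self.subject,
            "condition": self.condition,
            "gamma_median": self.gamma_median,
            "P_o_median": [float(v) for v in self.p_o_median],
            "exceedance": [float(v) for v in self.X],
            "map_numax": self.map_numax,
            "class": self.binary_class,
        }


def subject_posteriors(fit: FitResult) -> list[SubjectPosterior]:
    out = []
    for i, subject in enumerate(fit.subjects):
        X = exceedance(fit.resp[:, i, :])
        p_med = np.median(fit.p[:, i, :], axis=0)
        p_med = p_med / p_med.sum()
        out.append(
            SubjectPosterior(
                subject=subject,
                condition=fit.conditions[i],
                gamma_median=float(np.median(fit.gamma[:, i])),
                p_o_median=preference_transform(p_med).vector,
                X=X,
                map_numax=int(np.argmax(X)) + 1,
                binary_class=classify(X),
            )
        )
    return out


def confusion_experiment(
    n_per_class: int,
    condition: str,
    schedule_pair=None,
    settings: SamplerSettings | None = None,
    seed: int = 0,
    gamma: float = 5.0,
    p_o=(0.1, 0.6, 0.15, 0.15),
    flexible_values: tuple[int, ...] = (2, 4, 6, 8, 10),
    n_schedule_candidates: int = 20,
    return_details: bool = False,
):
    """Simulate known-nu_max agents, invert, and score binary classification.

    Half the simulated cohort has the maximally irregular prior
    (nu_max = 1) and half cycles through ``flexible_values``; all share
    gamma and P_o.  Returns per-true-class accuracy of the binarised
    exceedance classification.
    """
    from .task import make_condition_pair

    rng = np.random.default_rng(seed)
    if schedule_pair is None:
        schedule_pair = make_condition_pair(
            int(rng.integers(2**31)), n_candidates=n_schedule_candidates
        )
    sched, table = schedule_pair[condition]
    prefs = Preferences(p_o[0], p_o[1], p_o[2] + p_o[3])
    true_nu: list[int] = [1] * n_per_class + [
        flexible_values[i % len(flexible_values)] for i in range(n_per_class)
    ]
    caches = []
    for i, nu in enumerate(true_nu):
        cfg = AgentConfig(nu_max=nu, gamma=gamma, preferences=prefs)
        res = run_agent(cfg, sched, table, seed=int(rng.integers(2**31)), subject=f"sim{i}")
        caches.append(build_likelihood_cache(res.records, condition=condition))
    fit = fit_hierarchical(caches, settings=settings, seed=int(rng.integers(2**31)))
    posts = subject_posteriors(fit)
    pred = np.array([p.binary_class == "numax>1" for p in posts])
    truth = np.array([nu > 1 for nu in true_nu])
    acc = {
        "numax=1": float(np.mean(pred[~truth] == False)),  # noqa: E712
        "numax>1": float(np.mean(pred[truth] == True)),  # noqa: E712
    }
    if return_details:
        return acc, {"true_nu": true_nu, "posteriors": posts, "fit": fit}
    return acc
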