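# Methods

## The task

A dynamic probabilistic reversal learning task with 1000 trials.  Two
cards carry anti-correlated reward probabilities (p_H = 0.8 for the
currently correct card, p_L = 0.2 for the other); which card is correct
is a latent binary context s1 that reverses at latent moments.  A third,
information-only option ("explore") returns a cue naming the currently
correct card and never pays or costs money.  Outcomes are coded 1 (loss),
2 (gain), 3 (cue: left correct), 4 (cue: right correct); choices 1 (left),
2 (explore), 3 (right).

Two between-subject conditions share the same mean interval between
reversals (20 trials) and differ only in regularity: *irregular* draws
intervals from a geometric distribution, *regular* from a negative
binomial.  The first 800 trials follow the condition's own law; trials
801–1000 replay the reversal series of the opposite condition's first
200 trials, so every subject experiences a statistics switch.  Outcome
tables are frozen: they are drawn once per condition and replayed
identically to every agent, removing outcome noise from between-agent
comparisons.

The deployed schedule per condition is selected from a batch of seeded
candidates to maximise the performance difference between a probe agent
with the condition-correct temporal representation and one with the
opposite representation.  The selection procedure is exact at any batch
size; the default batch is 20 candidates, a deliberate desk-scale choice
(the screening objective is a noisy two-run estimate anyway, and the
selected schedules are statistical stand-ins for the originally deployed
ones, which are not bundled here).

## The agent's generative model

The agent factorises each trial into:

- context s1 in {1, 2} — which card is correct;
- choice state s2 in {1, 2, 3} — set deterministically by the action;
- phase f in {1, …, nu + 1} — a latent counter gating reversals;
- temporal template m = (mu, nu) — a hypothesis about reversal statistics;
- outcome contingencies rho[s1, s2] — Dirichlet-distributed categorical
  outcome probabilities.

**Temporal templates.**  Each template represents the interval d between
reversals as a discrete phase-type distribution: per trial the phase
advances with probability delta = nu / (mu + nu) or stays, and the
context flips exactly when the end phase nu + 1 is occupied, after which
the phase re-initialises.  The resulting interval law is the shifted
negative binomial p(d) = C(d + nu − 2, d − 1) (1 − delta)^(d−1) delta^nu
with mean mu + 1 and variance mu + mu²/nu; nu = 1 is the geometric
(hidden-Markov) limit.  The segment-start distribution is chosen as the
Binomial(nu, delta) pmf over f − 1.  This is the distribution that makes
the phase chain's first-passage law equal the negative binomial exactly
on its full support d ≥ 1 (verified in the test suite for all 410 grid
templates to total variation < 1e−9); putting all mass on phase 1 would
shift the support to d ≥ nu + 1.  Pmf evaluations use log-space
binomial coefficients so d up to several thousand stays finite.

The derived reversal hazard delta_m[tau] — the probability that a
reversal occurs tau trials after one, obtained by propagating the phase
chain from the segment-start distribution — is constant 1/(mu + 1) for
nu = 1 and oscillates with period ≈ mu + 1 for large nu.  We define this
quantity as a hazard (probability of a transition at trial t + tau)
rather than as occupancy of the flipped context, because only the hazard
reading is constant in the geometric limit and matches the periodic
anticipation signal the agent exploits.

**Template grid and prior.**  Templates span mu in {5, …, 45} (41
values) times nu in {1, …, 10}.  The prior factorises: uniform over the
41-point mu grid times uniform over nu ≤ nu_max and zero above.  The
agent-level parameter nu_max in {1, …, 10} is the object of inference in
the population model: nu_max = 1 agents cannot represent regularity at
all.  (The uniform mu weight is exactly 1/41 over the 41-element grid.)

**Outcome model.**  Outcomes are categorical with Dirichlet priors per
(s1, s2).  Defaults encode training experience: the correct card pairing
starts at counts (loss 6, gain 32, cues 1, 1) — prior mean gain
probability 32/40 = 0.8 — the incorrect pairing at the mirror image, and
the explore arm at count 2 on the state-consistent cue with 0.01 on the
other three outcomes (near-certain that exploring yields a cue, and which
cue follows the context).  All counts are configurable.

## Belief updating

Per trial, beliefs over (m, s1, f) are propagated through each template's
phase kernel (prediction), updated by exact Bayes against the observed
outcome using the Dirichlet-marginalised likelihood mu[s1, s2, o] =
alpha / sum(alpha), and the Dirichlet counts of the chosen action and
observed outcome are incremented by the posterior context probability
q(s1) — exactly one unit of count mass per trial.  The template marginal
rides along in the joint; no per-template re-normalisation is needed.
Belief arrays are padded to the widest template (11 phases) so the whole
410-template grid updates in a handful of vectorised operations.

At trial 1 the phase distribution per template is the segment-start
distribution (as if a reversal had just completed); a uniform-phase
initialisation is available by configuration.  Missing responses
propagate beliefs by prediction only, without an outcome update, and are
excluded from any likelihood.  Template beliefs are never reset at the
trial-800 statistics switch.

## Action selection

One-step-ahead expected free energy per action:

    G(a) = KL( mu_bar(.|a) || P_o )  +  ambiguity(a)

where mu_bar is the predictive outcome distribution (context-marginal of
the count means), P_o = (p−, p+, p_c/2, p_c/2) are outcome preferences,
and ambiguity is the expected entropy of the outcome likelihood under the
Dirichlet beliefs, computed with the identity E_Dir[x ln x] =
mu (psi(alpha + 1) − psi(1 + sum alpha)).  Actions are sampled from
softmax(−gamma G); gamma is the choice precision (the sign convention is
fixed by the requirement that high-gamma agents approximately minimise
G).  Zero preference entries are floored at 1e−10 inside the logarithm so
G stays finite; the affected outcomes carry near-zero predictive mass.
Risk and ambiguity are the computed objects; the epistemic/novelty
decomposition of the same quantity is interpretive and not returned
separately.

## Behavioral measures

Performance is the odds of choosing the currently high-reward card and
probing the odds of choosing the explore option, both in a sliding
201-trial centered window (an odd window is required for exact centering;
the length is configurable).  Windows truncate at the series edges; the
within-window proportion is clipped to [1/(n+1), n/(n+1)] before the odds
transform, so runs of identical labels remain finite.  Explore and
missing choices count as not-correct for performance; missing trials are
excluded from numerator and denominator.  Summary means cover trials
400–800, dropping task familiarisation and the post-switch tail.
Temporal-representation quality is the RMSE of the template posterior
about the generative (mu, nu) at trial 800.

## Hierarchical inversion

For a subject's full choice/outcome sequence the belief trajectory is
independent of (gamma, P_o); it depends only on nu_max.  The package
therefore replays each subject once per candidate nu_max and caches, for
every likelihood trial (400–1000), the predictive outcome matrices and
ambiguity terms from which G — and the softmax choice likelihood — is
reconstructed in closed form for any (gamma, P_o).  This caching is exact,
not an approximation, and reduces each MCMC likelihood evaluation to
cheap array algebra.

The population model treats nu_max as a random effect: per condition a
Dirichlet weight vector r over the ten values with concentration 1/tau
(tau half-Cauchy(0, 1); tau → 0 forces r to uniform 1/10), per subject
gamma ~ Inverse-Gamma(2, 2) and a flat Dirichlet 3-simplex p mapped to
preferences via P_o = (p1/2, p1/2 + p2, p3/2, p3/2), which enforces
p+ ≥ p−.  nu_max is marginalised out of the likelihood (a 10-component
mixture per subject).

**Sampler.**  The posterior is drawn with a collapsed
Metropolis-within-Gibbs scheme: each subject's (log gamma, p) block is
updated by adaptive random-walk Metropolis against the nu-marginalised
likelihood (Haario-style covariance adaptation during warmup, step size
tuned to ~0.3 acceptance, two to three proposals per sweep); the nu_max
indicators are then redrawn from their exact categorical conditionals,
the condition weights r from their conjugate Dirichlet conditionals, and
log tau by adaptive random-walk Metropolis.  Every step leaves the
augmented posterior invariant, and the continuous draws target exactly
the marginalised model.  Defaults: 4 chains × (500 warmup + 500 kept);
split R-hat is computed on log tau and the per-subject log gamma and a
warning is raised above 1.05.  Simplices are handled by a fixed-last
softmax transform with the exact Jacobian; gamma and tau on the log
scale.

Per kept sample the responsibility p_s(nu_max = nu | data) combines the
sampled mixture weights with the per-component log-likelihoods in log
space.  The exceedance probability X_i is the fraction of samples in
which component i has the largest responsibility (argmax ties break
toward smaller nu, favouring the simpler hidden-Markov hypothesis), and
the binary class is nu_max = 1 versus nu_max > 1 by the argmax of X.
A summed-class-probability binarisation would also be defensible; the
argmax-of-exceedance rule is adopted because it is the sharper and more
conventional random-effects model-selection statistic.

**Confusion experiment.**  Cohorts of 10 + 10 agents per condition
(nu_max = 1 versus nu_max cycled over {2, 4, 6, 8, 10}), gamma = 5,
P_o = (0.1, 0.6, 0.15, 0.15), simulated on the condition's frozen
schedule, cached, fitted, and classified.  The acceptance script runs
the sampler at 4 × (250 + 250) with three proposals per block — a
reduced, diagnostically adequate setting whose results are stable for
the binary classification question even where individual gamma chains
still show R-hat slightly above 1.05.

## What the generator does and does not emulate

The synthetic cohorts are ideal-observer agents of the same family as
the fitted model, run on frozen schedules with exactly the stated
parameters.  Passing classification checks therefore demonstrates that
the inversion machinery recovers known generative classes at realistic
trial counts — not that human data are generated by this model.  Real
behavior adds non-stationary strategies, lapses, and reaction-time
structure that the generator deliberately omits; missing responses are
supported in the inversion path but are never generated.

## Numerical choices and limitations

- Belief normalisation is enforced to 1e−8 over full runs; exact Bayes
  updates raise on zero evidence (inconsistent counts) rather than
  renormalising silently.
- The likelihood uses trials 400–1000 (1-based, inclusive); belief
  trajectories always use all trials.
- Desk-scale defaults (20 schedule candidates, 20-run sweeps, reduced
  MCMC) are the package's own problem sizes; the study-scale settings
  (10^5 candidates, 50-run sweeps) are available through the same
  interfaces and a `--paper-scale` CLI flag where applicable.
- Continuous-time phase-type durations (real-time semi-Markov dynamics)
  are out of scope; the phase counter abstracts elapsed time in trials.
- Multi-step planning is not implemented: expected free energy is
  one-step-ahead, appropriate because actions do not influence context
  transitions in this task.
- The random-walk sampler is exact but less efficient than a
  gradient-based sampler on the same marginalised model; convergence is
  monitored and reported, and settings are fully configurable.
- **Identifiability in the irregular condition.**  The nu_max hypotheses
  are nested: a flexible agent exposed to geometric reversals learns
  nu ≈ 1 within a few hundred trials and thereafter behaves like the
  nu_max = 1 agent, so the likelihood over trials 400–1000 separates the
  classes by only fractions of a nat per subject (versus tens of nats in
  the regular condition, measured at the true generating parameters).
  Irregular-condition classification accuracies at desk scale therefore
  reflect a nearly flat posterior and fluctuate across seeds; only the
  regular-condition classification is a sharp test of the inversion
  machinery.  Enlarging the schedule-screening batch (20 → 300
  candidates) did not measurably increase this separation.
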