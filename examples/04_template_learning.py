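"""Watch a flexible agent learn the latent temporal structure.

The agent's posterior over templates q_t(mu, nu) is marginalised per trial;
in the regular condition the mode of q(mu) homes in on the generative mean
(mu = 19) within ~200 trials, while q(nu) takes longer to concentrate on
regular templates.
"""

from temporev import MU_GRID, NU_GRID, make_condition_pair, run_template_learning

pair = make_condition_pair(seed=1, n_candidates=5)

for condition in ("regular", "irregular"):
    q_mu, q_nu, _ = run_template_learning(
        condition=condition, seed=0, schedule_pair=pair
    )
    for trial in (200, 800):
        mu_hat = MU_GRID[q_mu[trial - 1].argmax()]
        nu_hat = NU_GRID[q_nu[trial - 1].argmax()]
        print(
            f"{condition:>9} trial {trial:4d}: mode q(mu) = {mu_hat}, "
            f"mode q(nu) = {nu_hat}"
        )
# Generative truth: mu = 19 in both conditions; nu = 10 (regular) or 1
# (irregular).  The mu estimate is available early; the regularity
# estimate sharpens later and flips to nu = 1 in the irregular condition.
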