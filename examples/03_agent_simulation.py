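"""Simulate agents with different temporal priors and score their behavior.

nu_max bounds the regularity an agent can represent a priori: nu_max = 1
is the hidden-Markov agent (reversals unpredictable), nu_max = 10 can
learn to anticipate regular reversals.
"""

from temporev import (
    AgentConfig,
    Preferences,
    make_condition_pair,
    performance_series,
    probing_series,
    run_agent,
    summary_means,
)

pair = make_condition_pair(seed=1, n_candidates=5)
sched, table = pair["regular"]
prefs = Preferences(0.1, 0.6, 0.3)  # P_o = (0.1, 0.6, 0.15, 0.15)

for nu_max in (1, 10):
    cfg = AgentConfig(nu_max=nu_max, gamma=5.0, preferences=prefs)
    res = run_agent(cfg, sched, table, seed=3)
    perf = summary_means(performance_series(res.records))
    probe = summary_means(probing_series(res.records))
    print(
        f"nu_max={nu_max:2d}: performance odds {perf:.2f}, "
        f"probing odds {probe:.3f} (trials 400-800)"
    )
# The flexible agent anticipates reversals and earns higher odds of
# choosing the high-reward card.  Single runs are noisy; the nu_max sweep
# (run_numax_sweep, 20+ runs) shows the systematic ordering of both
# measures, including lower probing for flexible agents.
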