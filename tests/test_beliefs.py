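"""Belief initialisation, prediction, Bayes updates, and Dirichlet learning."""

import numpy as np
import pytest

from temporev import (
    AgentConfig,
    MU_GRID,
    NU_GRID,
    default_alpha0,
    init_beliefs,
    predict,
    template_marginals,
    update_dirichlet,
    update_state_beliefs,
)
from temporev.beliefs import DirichletCounts, _GridArrays
from temporev.templates import phase_kernel, template_prior


@pytest.fixture
def belief10():
    return init_beliefs(AgentConfig(nu_max=10))


def dense_transition_oracle(belief):
    """Brute-force prediction: per template, build the full (s1 x f) joint
    transition matrix from the phase kernel and the flip-from-end-phase rule
    and apply it by dense matrix multiplication."""
    arrays = belief._arrays
    grid = arrays.grid
    out = np.zeros_like(belief.joint)
    for i, tpl in enumerate(grid.templates):
        n = tpl.n_phases
        K = phase_kernel(tpl).advance_stay
        q = belief.joint[i, :, :n]  # (2, n)
        T = np.zeros((2 * n, 2 * n))
        for s in range(2):
            for f in range(n):
                s_next = 1 - s if f == n - 1 else s
                for f2 in range(n):
                    T[s * n + f, s_next * n + f2] += K[f, f2]
        v = q.reshape(-1) @ T
        out[i, :, :n] = v.reshape(2, n)
    return out


class TestInit:
    def test_hmm_limit_support(self):
        b = init_beliefs(AgentConfig(nu_max=1))
        grid = template_prior(10)
        assert np.all(b.joint[grid.nus > 1] == 0)

    def test_symmetric_state_prior(self, belief10):
        assert np.allclose(belief10.state_marginal(), [0.5, 0.5])

    def test_normalized(self, belief10):
        assert np.isclose(belief10.joint.sum(), 1.0, atol=1e-12)

    def test_uniform_phase_option(self):
        b = init_beliefs(AgentConfig(nu_max=2, init_phase="uniform"))
        assert np.isclose(b.joint.sum(), 1.0, atol=1e-12)


class TestPredict:
    def test_end_phase_flips_state_with_certainty(self):
        b = init_beliefs(AgentConfig(nu_max=10))
        idx = 100  # some template
        nu = b._arrays.end[idx]
        joint = np.zeros_like(b.joint)
        joint[idx, 0, nu] = 1.0  # all mass on (s1=1, end phase)
        b.joint = joint
        b.is_predictive = False
        pred = predict(b)
        assert np.isclose(pred.state_marginal()[1], 1.0, atol=1e-12)

    def test_below_end_phase_keeps_state_marginal(self):
        b = init_beliefs(AgentConfig(nu_max=10))
        idx = 400  # nu = 10 template
        joint = np.zeros_like(b.joint)
        joint[idx, 0, 2] = 0.7
        joint[idx, 1, 4] = 0.3
        b.joint = joint
        b.is_predictive = False
        pred = predict(b)
        assert np.allclose(pred.state_marginal(), [0.7, 0.3], atol=1e-12)

    def test_matches_dense_matrix_oracle(self, rng):
        b = init_beliefs(AgentConfig(nu_max=10))
        raw = rng.random(b.joint.shape) * b._arrays.valid[:, None, :]
        b.joint = raw / raw.sum()
        b.is_predictive = False
        pred = predict(b)
        oracle = dense_transition_oracle(b)
        assert np.max(np.abs(pred.joint - oracle)) < 1e-12

    def test_template_marginal_carried_forward(self, rng):
        b = init_beliefs(AgentConfig(nu_max=10))
        raw = rng.random(b.joint.shape) * b._arrays.valid[:, None, :]
        b.joint = raw / raw.sum()
        b.is_predictive = False
        pred = predict(b)
        assert np.allclose(pred.template_marginal(), b.template_marginal(), atol=1e-12)

    def test_rejects_unnormalized(self, belief10):
        belief10.joint = belief10.joint * 2
        belief10.is_predictive = False
        with pytest.raises(ValueError):
            predict(belief10)


class TestStateUpdate:
    def test_flat_likelihood_leaves_joint_unchanged(self, belief10):
        alpha = belief10.counts.table
        alpha[:] = 1.0  # symmetric counts: identical likelihood for both s1
        post, ev = update_state_beliefs(belief10, 1, 2)
        assert np.allclose(post.joint, belief10.joint, atol=1e-12)
        assert np.isclose(ev, 0.25)

    def test_cue_reveals_state(self, belief10):
        post, _ = update_state_beliefs(belief10, 2, 3)  # explore, cue-left
        assert post.state_marginal()[0] > 0.99

    def test_matches_enumeration_oracle(self, rng, belief10):
        raw = rng.random(belief10.joint.shape) * belief10._arrays.valid[:, None, :]
        belief10.joint = raw / raw.sum()
        choice, outcome = 3, 1
        mu = belief10.counts.outcome_probs()
        oracle = np.array(
            [
                [
                    belief10.joint[m, s] * mu[s, choice - 1, outcome - 1]
                    for s in range(2)
                ]
                for m in range(belief10.joint.shape[0])
            ]
        )
        oracle = oracle / oracle.sum()
        post, ev = update_state_beliefs(belief10, choice, outcome)
        assert np.max(np.abs(post.joint - oracle)) < 1e-12
        assert 0 < ev < 1

    def test_inconsistent_choice_outcome(self, belief10):
        with pytest.raises(ValueError):
            update_state_beliefs(belief10, 1, 3)  # card choice, cue outcome
        with pytest.raises(ValueError):
            update_state_beliefs(belief10, 2, 2)  # explore, gain outcome


class TestDirichletUpdate:
    def test_certain_state_unit_increment(self, belief10):
        joint = np.zeros_like(belief10.joint)
        joint[0, 0, 0] = 1.0  # q(s1) = (1, 0)
        belief10.joint = joint
        belief10.is_predictive = False
        before = belief10.counts.table.copy()
        counts = update_dirichlet(belief10, 1, 2)
        diff = counts.table - before
        assert np.isclose(diff[0, 0, 1], 1.0)
        diff[0, 0, 1] = 0.0
        assert np.all(diff == 0.0)

    def test_soft_state_weighted_increment(self, belief10):
        joint = np.zeros_like(belief10.joint)
        joint[0, 0, 0] = 0.3
        joint[0, 1, 0] = 0.7
        belief10.joint = joint
        belief10.is_predictive = False
        before = belief10.counts.table.copy()
        counts = update_dirichlet(belief10, 3, 1)
        diff = counts.table - before
        assert np.isclose(diff[0, 2, 0], 0.3) and np.isclose(diff[1, 2, 0], 0.7)
        assert np.isclose(diff.sum(), 1.0)

    def test_unchosen_columns_keep_prior(self, short_run):
        # columns of actions the simulated agent never took must equal alpha0
        chosen = set(short_run.records["choice"])
        alpha0 = default_alpha0()
        for a in {1, 2, 3} - chosen:
            assert np.allclose(
                short_run.final_belief.counts.table[:, a - 1, :], alpha0[:, a - 1, :]
            )

    def test_positive_counts_enforced(self):
        with pytest.raises(ValueError):
            DirichletCounts(np.zeros((2, 3, 4)))


class TestTemplateMarginals:
    def test_hmm_agent_point_mass_on_nu1(self):
        b = init_beliefs(AgentConfig(nu_max=1))
        _, q_nu = template_marginals(b)
        assert np.isclose(q_nu[0], 1.0)

    def test_uniform_joint_gives_uniform_mu(self, belief10):
        q_mu, q_nu = template_marginals(belief10)
        assert np.allclose(q_mu, 1.0 / 41.0)
        assert np.isclose(q_mu.sum(), 1.0) and np.isclose(q_nu.sum(), 1.0)


class TestLongRunProperties:
    def test_normalization_over_full_run(self, short_run):
        assert abs(short_run.final_belief.joint.sum() - 1.0) < 1e-8

    def test_template_learning_by_condition(self, condition_pair):
        """A flexible agent concentrates q(mu) near the generative mean and
        q(nu) on regular templates in the regular condition, and on nu = 1
        in the irregular condition (majority over 5 seeded runs)."""
        from temporev import Preferences, run_agent

        cfg = AgentConfig(nu_max=10, gamma=5.0, preferences=Preferences(0.1, 0.6, 0.3))
        hits_reg, hits_irr = 0, 0
        for seed in range(5):
            sched, table = condition_pair["regular"]
            res = run_agent(cfg, sched, table, seed=seed, track_beliefs=True)
            mu_hat = MU_GRID[res.q_mu[799].argmax()]
            nu_hat = NU_GRID[res.q_nu[799].argmax()]
            hits_reg += (abs(mu_hat - 19) <= 2) and (nu_hat > 1)
            sched, table = condition_pair["irregular"]
            res = run_agent(cfg, sched, table, seed=seed, track_beliefs=True)
            hits_irr += NU_GRID[res.q_nu[799].argmax()] <= 2
        assert hits_reg >= 3
        assert hits_irr >= 3
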