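"""Dropout masks and the Beta-Bernoulli gated RBM with its Gibbs conditionals."""

import numpy as np
import pytest
from scipy import stats as sps

from semnet import rbm
from semnet.ibp import (
    IBPState,
    beta_shape_parameters,
    ibp_cd_step,
    ibp_energy,
    joint_hz_conditional,
    sample_dropout_mask,
    sample_hz,
    sample_ibp_prior,
    sample_pi_posterior,
)
from semnet.rbm import RBMParams, cd_gradient, enumerate_binary_states

from conftest import random_tiny_rbm


class TestDropoutMask:
    def test_extreme_rates(self, rng):
        assert np.all(sample_dropout_mask(50, 0.0, rng).mask == 1.0)
        assert np.all(sample_dropout_mask(50, 1.0, rng).mask == 0.0)

    def test_active_fraction_matches_keep_probability(self, rng):
        K, rate = 10_000, 0.3
        mask = sample_dropout_mask(K, rate, rng)
        tol = 3 * np.sqrt(rate * (1 - rate) / K)
        assert abs(mask.mask.mean() - (1 - rate)) < tol

    def test_invalid_rate_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_dropout_mask(10, 1.5, rng)


class TestIBPPrior:
    def test_prior_mean_matches_beta_closed_form(self, rng):
        alpha, beta, K = 2.0, 3.0, 16
        draws = np.concatenate(
            [sample_ibp_prior(K, alpha, beta, rng).pi for _ in range(700)]
        )
        mean = alpha / (alpha + beta * (K - 1))
        a, b = beta_shape_parameters(alpha, beta, K)
        se = np.sqrt(sps.beta(a, b).var() / draws.size)
        assert abs(draws.mean() - mean) < 3 * se

    def test_default_hyperparameters_are_strongly_sparse(self, rng):
        # alpha=1, beta=5, K=1024: expected active fraction ~ 1/(1 + 5*1023)
        state = sample_ibp_prior(1024, 1.0, 5.0, rng, n_instances=50)
        expected = 1.0 / (1.0 + 5.0 * 1023)
        assert expected == pytest.approx(1.954e-4, rel=1e-3)
        assert state.z.mean() < 20 * expected  # sparse; loose bound, tiny rate

    def test_degenerate_single_unit_guarded(self, rng):
        state = sample_ibp_prior(1, 1.0, 5.0, rng)
        assert np.all((state.pi > 0) & (state.pi < 1))
        assert np.isfinite(state.pi).all()


class TestIBPEnergy:
    def test_all_zero_gate_leaves_visible_term_only(self, rng):
        p = random_tiny_rbm(rng)
        v = rng.random(4)
        e = ibp_energy(p, v, np.ones(3), np.zeros(3))
        assert e == pytest.approx(-float(p.visible_bias @ v), abs=1e-12)

    def test_all_ones_gate_reduces_to_plain_energy(self, rng):
        p = random_tiny_rbm(rng)
        v = (rng.random(4) < 0.5).astype(float)
        h = (rng.random(3) < 0.5).astype(float)
        assert ibp_energy(p, v, h, np.ones(3)) == pytest.approx(
            rbm.energy(p, v, h), abs=1e-12
        )

    def test_matches_term_by_term_summation(self, rng):
        p = random_tiny_rbm(rng)
        v, h, z = rng.random(4), np.array([1.0, 0, 1]), np.array([1.0, 1, 0])
        expected = 0.0
        for k in range(3):
            for i in range(4):
                expected -= z[k] * h[k] * p.weights[k, i] * v[i]
            expected -= p.hidden_bias[k] * z[k] * h[k]
        for i in range(4):
            expected -= p.visible_bias[i] * v[i]
        assert ibp_energy(p, v, h, z) == pytest.approx(expected, abs=1e-10)


class TestJointHZConditional:
    def test_symmetric_case_is_uniform(self):
        p = RBMParams(np.zeros((2, 2)), np.zeros(2), np.zeros(2))
        table = joint_hz_conditional(p, np.zeros(2), 0.5, 0)
        assert np.allclose(table, 0.25)

    def test_hand_normalized_weights(self):
        p = RBMParams(np.zeros((2, 2)), np.zeros(2), np.zeros(2))
        table = joint_hz_conditional(p, np.zeros(2), 0.8, 1)
        # weights: (1,1)=0.8, (0,1)=0.8, (0,0)=0.2, (1,0)=0.2, total 2
        assert table[1, 1] == pytest.approx(0.4)
        assert table[0, 1] == pytest.approx(0.4)
        assert table[0, 0] == pytest.approx(0.1)
        assert table[1, 0] == pytest.approx(0.1)
        assert table[:, 1].sum() == pytest.approx(0.8)  # marginal p(z=1)

    def test_mass_concentrates_when_pi_high_and_drive_large(self):
        p = RBMParams(np.array([[50.0]]), np.zeros(1), np.zeros(1))
        table = joint_hz_conditional(p, np.ones(1), 1 - 1e-9, 0)
        assert table[1, 1] > 0.999999

    def test_table_sums_to_one(self, rng):
        p = random_tiny_rbm(rng)
        for k in range(3):
            table = joint_hz_conditional(p, rng.random(4), rng.uniform(0.1, 0.9), k)
            assert abs(table.sum() - 1.0) < 1e-12

    def test_matches_gated_energy_enumeration(self, rng):
        # With the other units' gates fixed to zero, the (h_k, z_k)
        # conditional follows the Boltzmann weights of ibp_energy directly.
        p = random_tiny_rbm(rng, n_visible=3, n_hidden=1)
        v = rng.random(3)
        pi_k = 0.37
        weights = np.zeros((2, 2))
        for a in (0, 1):
            for b in (0, 1):
                boltz = np.exp(-ibp_energy(p, v, np.array([a]), np.array([b])))
                prior = pi_k if b == 1 else 1 - pi_k
                weights[a, b] = prior * boltz
        # the pure-visible factor is common to all four states and cancels
        expected = weights / weights.sum()
        table = joint_hz_conditional(p, v, pi_k, 0)
        assert np.allclose(table, expected, atol=1e-12)


class TestSampleHZ:
    def test_frequencies_match_analytic_table(self, rng):
        p = random_tiny_rbm(rng, n_visible=3, n_hidden=2, scale=0.7)
        v = rng.random(3)
        pi = np.array([0.3, 0.7])
        n = 20_000
        h, z = sample_hz(p, np.tile(v, (n, 1)), pi, rng)
        for k in range(2):
            table = joint_hz_conditional(p, v, pi[k], k)
            counts = np.zeros((2, 2))
            for a in (0, 1):
                for b in (0, 1):
                    counts[a, b] = np.sum((h[:, k] == a) & (z[:, k] == b))
            for a in (0, 1):
                for b in (0, 1):
                    pexp = table[a, b]
                    se = np.sqrt(pexp * (1 - pexp) / n)
                    assert abs(counts[a, b] / n - pexp) < 3 * se + 1e-9

    def test_high_pi_zero_drive_limits(self, rng):
        p = RBMParams(np.zeros((3, 2)), np.zeros(2), np.zeros(3))
        pi = np.full(3, 1 - 1e-12)
        h, z = sample_hz(p, np.zeros((4000, 2)), pi, rng)
        assert z.mean() > 0.999
        assert abs(h.mean() - 0.5) < 0.03

    def test_seed_reproducibility(self, rng):
        p = random_tiny_rbm(rng)
        pi = np.array([0.2, 0.5, 0.9])
        v = rng.random(4)
        h1, z1 = sample_hz(p, v, pi, np.random.default_rng(11))
        h2, z2 = sample_hz(p, v, pi, np.random.default_rng(11))
        assert h1.shape == (3,)
        assert np.array_equal(h1, h2) and np.array_equal(z1, z2)


class TestPiPosterior:
    def test_no_data_reduces_to_prior(self, rng):
        alpha, beta, K = 1.5, 4.0, 8
        a, b = beta_shape_parameters(alpha, beta, K)
        draws = np.stack(
            [sample_pi_posterior(alpha, beta, K, np.zeros(K), 0, rng) for _ in range(2000)]
        )
        ref = sps.beta(a, b)
        se = np.sqrt(ref.var() / draws.size)
        assert abs(draws.mean() - ref.mean()) < 4 * se

    def test_posterior_shapes_for_reference_setting(self):
        # alpha=1, beta=5, K=1024, M=20, sum z = 10
        a, b = beta_shape_parameters(1.0, 5.0, 1024)
        assert a + 10 == pytest.approx(10 + 1 / 1024)
        assert b + 10 == pytest.approx(10 + 5 * 1023 / 1024)

    def test_posterior_mean_matches_grid_integration(self, rng):
        alpha, beta, K, M, s = 1.0, 5.0, 16, 12, 5
        a0, b0 = beta_shape_parameters(alpha, beta, K)
        grid = np.linspace(1e-6, 1 - 1e-6, 10_000)
        post = sps.beta(a0, b0).pdf(grid) * grid**s * (1 - grid) ** (M - s)
        grid_mean = np.sum(grid * post) / np.sum(post)
        analytic = (a0 + s) / (a0 + s + b0 + M - s)
        assert abs(grid_mean - analytic) < 1e-3
        draws = np.concatenate(
            [sample_pi_posterior(alpha, beta, K, np.full(K, s), M, rng) for _ in range(100)]
        )
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - grid_mean) < 4 * se

    def test_out_of_range_counts_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_pi_posterior(1.0, 5.0, 4, np.array([5.0, 0, 0, 0]), 4, rng)

    def test_gibbs_chain_preserves_analytic_beta(self, rng):
        # With z fixed, repeated conjugate draws are i.i.d. from the analytic
        # Beta; the KS test must not reject at the 1% level.
        alpha, beta, K, M = 1.0, 5.0, 32, 40
        z_sums = np.full(K, 11.0)
        a0, b0 = beta_shape_parameters(alpha, beta, K)
        draws = np.concatenate(
            [sample_pi_posterior(alpha, beta, K, z_sums, M, rng) for _ in range(320)]
        )
        stat, pvalue = sps.kstest(draws, sps.beta(a0 + 11, b0 + M - 11).cdf)
        assert pvalue > 0.01


class TestIBPCDStep:
    def test_pinned_gate_reproduces_plain_cd(self, rng):
        p = random_tiny_rbm(rng, n_visible=5, n_hidden=4)
        batch = (rng.random((12, 5)) < 0.5).astype(float)
        state = IBPState(pi=np.ones(4), alpha=1.0, beta=5.0)  # clamped just inside 1
        g_plain = cd_gradient(p, batch, 1, np.random.default_rng(42))
        g_ibp, _ = ibp_cd_step(
            p, batch, state, 1, np.random.default_rng(42), resample_pi=False
        )
        assert np.allclose(g_plain.weights, g_ibp.weights, atol=1e-9)
        assert np.allclose(g_plain.hidden_bias, g_ibp.hidden_bias, atol=1e-9)
        assert np.allclose(g_plain.visible_bias, g_ibp.visible_bias, atol=1e-9)

    def test_null_case_gradient_near_zero(self, rng):
        # all-zero real-valued batch at the model's own mean: the data and
        # reconstruction phases coincide and the gradient vanishes
        p = RBMParams(np.zeros((3, 4)), np.zeros(4), np.zeros(3), "gaussian")
        batch = np.zeros((200, 4))
        state = IBPState(pi=np.full(3, 0.5), alpha=1.0, beta=1.0)
        g, _ = ibp_cd_step(p, batch, state, 1, rng, resample_pi=False)
        assert np.max(np.abs(g.weights)) < 0.05
        assert np.max(np.abs(g.hidden_bias)) < 0.05

    def test_sparsity_recovery_on_two_pattern_data(self):
        # Data made of 2 ground-truth binary patterns: with K=8 gated units,
        # the posterior should keep only a few units alive.
        successes = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            patterns = np.array(
                [[1.0, 1, 1, 1, 0, 0, 0, 0], [0.0, 0, 0, 0, 1, 1, 1, 1]]
            )
            data = patterns[rng.integers(0, 2, size=240)]
            flip = rng.random(data.shape) < 0.02
            data = np.abs(data - flip)
            params = RBMParams(
                rng.normal(0, 0.01, (8, 8)), np.zeros(8), np.zeros(8)
            )
            state = sample_ibp_prior(8, 1.0, 5.0, rng)
            opt = rbm.UpdateState.for_params(params, 0.5, 1.0, 0.05)
            pi_trace = []
            for epoch in range(60):
                for start in range(0, 240, 40):
                    g, state = ibp_cd_step(
                        params, data[start : start + 40], state, 1, rng, n_total=240
                    )
                    params = rbm.apply_update(params, g, opt)
                pi_trace.append(state.pi.copy())
            mean_pi = np.mean(pi_trace[-20:], axis=0)
            if np.sum(mean_pi > 0.5) <= 4:
                successes += 1
        assert successes >= 4

    def test_updates_state_z_for_batch(self, rng):
        p = random_tiny_rbm(rng, n_visible=3, n_hidden=2)
        batch = (rng.random((7, 3)) < 0.5).astype(float)
        state = sample_ibp_prior(2, 1.0, 5.0, rng)
        _, new_state = ibp_cd_step(p, batch, state, 1, rng)
        assert new_state.z.shape == (7, 2)
        assert np.all(np.isin(new_state.z, (0.0, 1.0)))


class TestPriorGibbsActivation:
    @pytest.mark.parametrize("alpha,beta,K", [(1.0, 5.0, 64), (2.0, 3.0, 128)])
    def test_uninformative_chain_matches_prior_mean(self, alpha, beta, K):
        # W = 0, b = 0: alternating (h, z) | pi and pi | z leaves the prior
        # marginal of z invariant; the long-run activation fraction must
        # match alpha / (alpha + beta (K - 1)).
        rng = np.random.default_rng(int(alpha * 100 + K))
        p = RBMParams(np.zeros((K, 2)), np.zeros(2), np.zeros(K))
        state = sample_ibp_prior(K, alpha, beta, rng)
        v = np.zeros(2)
        iters, burn = 3000, 200
        block_means = []
        zs = []
        for t in range(iters):
            h, z = sample_hz(p, v, state.pi, rng)
            pi = sample_pi_posterior(alpha, beta, K, z, 1, rng)
            state = IBPState(pi=pi, alpha=alpha, beta=beta)
            if t >= burn:
                zs.append(z.mean())
        zs = np.array(zs)
        target = alpha / (alpha + beta * (K - 1))
        # batch means over blocks absorb the chain's autocorrelation
        blocks = zs.reshape(-1, 100).mean(axis=1)
        se = blocks.std(ddof=1) / np.sqrt(blocks.size)
        assert abs(zs.mean() - target) < 3 * se + 1e-6
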