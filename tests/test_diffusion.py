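"""Forward process, reverse posterior, loss, and few-step sampler."""

import numpy as np
import pytest

from mocoshift import (
    ConstantDenoiser,
    LossValue,
    MotionConfig,
    PairedSample,
    ScheduleConfig,
    build_schedule,
    corrupt,
    forward_marginal_params,
    noise_level,
    posterior_params,
    sample_forward,
    sample_restore,
    training_loss,
    training_step,
    transition_sample,
)


def random_pair(rng, shape=(16, 16)):
    x = rng.random(shape)
    y = rng.random(shape)
    return PairedSample(x=x, y=y)


class TestPairedSample:
    def test_residual_computed(self):
        rng = np.random.default_rng(0)
        s = random_pair(rng)
        assert np.array_equal(s.r, s.y - s.x)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            PairedSample(x=np.zeros((4, 4)), y=np.zeros((5, 5)))

    def test_inconsistent_residual_rejected(self):
        with pytest.raises(ValueError):
            PairedSample(
                x=np.zeros((4, 4)), y=np.ones((4, 4)), r=np.zeros((4, 4))
            )


class TestForwardMarginal:
    def test_zero_residual_mean_is_x(self, train_schedule):
        x = np.random.default_rng(1).random((8, 8))
        s = PairedSample(x=x, y=x.copy())
        for t in (1, 10, 20):
            mean, _ = forward_marginal_params(s, train_schedule, t)
            assert np.array_equal(mean, x)

    def test_first_step_noise_is_tiny(self, train_schedule):
        """gamma*sqrt(beta_1) equals the printed 0.04, and the mean shift
        uses beta_1 = 4e-4."""
        rng = np.random.default_rng(2)
        s = random_pair(rng)
        mean, std = forward_marginal_params(s, train_schedule, 1)
        assert std == pytest.approx(0.04)
        assert np.allclose(mean, s.x + 0.0004 * s.r)

    def test_terminal_step_reaches_y(self, train_schedule):
        rng = np.random.default_rng(3)
        s = random_pair(rng)
        mean, std = forward_marginal_params(s, train_schedule, 20)
        assert std == pytest.approx(2 * np.sqrt(0.999))
        # mean = x + 0.999 r is within (1-betaN)*|r| of y
        assert np.all(np.abs(mean - s.y) <= (1 - 0.999) * np.abs(s.r) + 1e-15)

    def test_out_of_range_t(self, train_schedule):
        s = random_pair(np.random.default_rng(4))
        with pytest.raises(IndexError):
            forward_marginal_params(s, train_schedule, 0)
        with pytest.raises(IndexError):
            forward_marginal_params(s, train_schedule, 21)


class TestSampleForward:
    def test_deterministic_given_seed(self, train_schedule):
        s = random_pair(np.random.default_rng(5))
        a = sample_forward(s, train_schedule, 7, np.random.default_rng(99))
        b = sample_forward(s, train_schedule, 7, np.random.default_rng(99))
        assert np.array_equal(a.x_t, b.x_t)
        assert a.t == 7

    def test_monte_carlo_moments_match_closed_form(self, train_schedule):
        """Empirical mean and variance of a single pixel over 1e5 draws
        agree with x + beta_t r and gamma^2 beta_t within 3 s.e."""
        s = PairedSample(x=np.array([[0.3]]), y=np.array([[0.9]]))
        t = 12
        mean, std = forward_marginal_params(s, train_schedule, t)
        rng = np.random.default_rng(123)
        n = 100_000
        draws = np.array(
            [sample_forward(s, train_schedule, t, rng).x_t[0, 0] for _ in range(n)]
        )
        se_mean = std / np.sqrt(n)
        assert abs(draws.mean() - mean[0, 0]) < 3 * se_mean
        var = std**2
        se_var = var * np.sqrt(2 / (n - 1))
        assert abs(draws.var() - var) < 3 * se_var


class TestTransition:
    def test_identity_when_no_residual_no_noise(self, train_schedule):
        x = np.random.default_rng(6).random((8, 8))

        class ZeroRng:
            def standard_normal(self, shape):
                return np.zeros(shape)

        out = transition_sample(x, np.zeros_like(x), train_schedule, 5, ZeroRng())
        assert np.array_equal(out, x)

    def test_single_step_std(self, train_schedule):
        """Empirical std of one transition matches gamma*sqrt(alpha_t)."""
        rng = np.random.default_rng(7)
        x = np.zeros((1, 1))
        r = np.zeros((1, 1))
        t = 9
        n = 100_000
        draws = np.array(
            [transition_sample(x, r, train_schedule, t, rng)[0, 0] for _ in range(n)]
        )
        target = train_schedule.gamma * np.sqrt(train_schedule.alphas[t])
        se = target * np.sqrt(1 / (2 * n))
        assert abs(draws.std() - target) < 3 * se

    def test_chained_transitions_match_marginal(self, train_schedule):
        """Composing the per-step kernels reproduces the direct marginal:
        means exactly (noise-free chain), pooled variances within 3 s.e."""
        rng = np.random.default_rng(8)
        s = random_pair(rng, shape=(16, 16))

        # means: telescoping with epsilon = 0
        class ZeroRng:
            def standard_normal(self, shape):
                return np.zeros(shape)

        x_chain = s.x.copy()
        for t in range(1, train_schedule.n_steps + 1):
            prev = s.x if t == 1 else x_chain
            x_chain = transition_sample(prev, s.r, train_schedule, t, ZeroRng())
            mean_direct, _ = forward_marginal_params(s, train_schedule, t)
            np.testing.assert_allclose(x_chain, mean_direct, rtol=1e-12, atol=1e-14)

        # variances: pooled over chains x pixels at every t
        m = 3000
        npix = s.x.size
        chains = np.broadcast_to(s.x, (m, *s.x.shape)).copy()
        r = np.broadcast_to(s.r, (m, *s.r.shape))
        for t in range(1, train_schedule.n_steps + 1):
            alpha = train_schedule.alphas[t]
            chains = chains + alpha * r + train_schedule.gamma * np.sqrt(
                alpha
            ) * rng.standard_normal(chains.shape)
            mean_direct, std_direct = forward_marginal_params(s, train_schedule, t)
            pooled_var = np.mean((chains - mean_direct) ** 2)
            var = std_direct**2
            se = var * np.sqrt(2 / (m * npix))
            assert abs(pooled_var - var) < 3 * se, f"variance mismatch at t={t}"


class TestPosterior:
    def test_final_step_collapses_to_estimate(self, train_schedule):
        rng = np.random.default_rng(9)
        x_t = rng.random((8, 8))
        x0 = rng.random((8, 8))
        mean, var = posterior_params(x_t, x0, train_schedule, 1)
        assert np.array_equal(mean, x0)
        assert var == 0.0

    def test_four_step_coefficients(self, sampler_schedule):
        """t=2 coefficients of the default 4-step schedule, frozen from
        the independently derived beta_2 ~ 0.111."""
        b1 = sampler_schedule.betas[1]
        b2 = sampler_schedule.betas[2]
        a2 = sampler_schedule.alphas[2]
        x_t = np.ones((2, 2))
        x0 = np.zeros((2, 2))
        mean, var = posterior_params(x_t, x0, sampler_schedule, 2)
        assert b1 / b2 == pytest.approx(0.0036, abs=2e-4)
        assert a2 / b2 == pytest.approx(0.9964, abs=2e-4)
        assert np.allclose(mean, b1 / b2)
        assert var == pytest.approx(1.6e-3, rel=0.1)
        assert var == pytest.approx(4.0 * (b1 / b2) * a2, rel=1e-12)

    @pytest.mark.parametrize("trial", range(20))
    def test_grid_bayes_oracle(self, train_schedule, trial):
        """Eq.-9-style parameters against a brute-force scalar Bayes
        computation: posterior(x_{t-1}) ~ transition(x_t | x_{t-1}) *
        marginal(x_{t-1}) evaluated on a fine grid."""
        rng = np.random.default_rng(1000 + trial)
        x = float(rng.uniform(0, 1))
        y = float(rng.uniform(0, 1))
        r = y - x
        t = int(rng.integers(2, train_schedule.n_steps + 1))
        g = train_schedule.gamma
        b_prev = train_schedule.betas[t - 1]
        b = train_schedule.betas[t]
        a = train_schedule.alphas[t]
        x_t = float(
            x + b * r + g * np.sqrt(b) * rng.standard_normal()
        )

        mean, var = posterior_params(
            np.array([[x_t]]), np.array([[x]]), train_schedule, t
        )
        # brute-force: product of the two Gaussian factors on a grid
        center = x + b_prev * r
        width = g * np.sqrt(b_prev)
        grid = np.linspace(center - 10 * width, center + 10 * width, 200_001)
        log_lik = -0.5 * ((x_t - (grid + a * r)) ** 2) / (g**2 * a)
        log_prior = -0.5 * ((grid - center) ** 2) / (g**2 * b_prev)
        w = np.exp(log_lik + log_prior - np.max(log_lik + log_prior))
        w /= w.sum()
        mean_num = float(np.sum(w * grid))
        var_num = float(np.sum(w * (grid - mean_num) ** 2))
        assert mean_num == pytest.approx(mean[0, 0], rel=1e-6, abs=1e-9)
        assert var_num == pytest.approx(var, rel=1e-6)

    def test_marginalization_identity(self, train_schedule):
        """Posterior composed over the marginal at t reproduces the
        marginal at t-1: (b_{t-1}/b_t)^2 g^2 b_t + g^2 b_{t-1} a_t / b_t
        = g^2 b_{t-1}, and the means telescope."""
        g = train_schedule.gamma
        for t in range(2, train_schedule.n_steps + 1):
            b_prev = train_schedule.betas[t - 1]
            b = train_schedule.betas[t]
            a = train_schedule.alphas[t]
            composed = (b_prev / b) ** 2 * g**2 * b + g**2 * (b_prev / b) * a
            assert composed == pytest.approx(g**2 * b_prev, rel=1e-12)


class TestTrainingLoss:
    def test_perfect_estimate_zero(self):
        x = np.random.default_rng(10).random((8, 8))
        loss = training_loss(x, x)
        assert loss.total == loss.l2_part == loss.l1_part == 0.0

    def test_constant_error_arithmetic(self):
        x = np.zeros((4, 4))
        f = np.full((4, 4), 0.5)
        loss = training_loss(f, x)
        assert loss.l2_part == pytest.approx(0.25)
        assert loss.l1_part == pytest.approx(0.5)
        assert loss.total == pytest.approx(0.75)

    def test_random_pair_against_recomputation(self):
        rng = np.random.default_rng(11)
        f = rng.random((16, 16))
        x = rng.random((16, 16))
        loss = training_loss(f, x)
        d = f - x
        assert loss.total == pytest.approx(
            float(np.mean(np.abs(d)) + np.mean(d**2)), rel=1e-12
        )

    def test_l2_only_drops_l1(self):
        rng = np.random.default_rng(12)
        f = rng.random((8, 8))
        x = rng.random((8, 8))
        loss = training_loss(f, x, l2_only=True)
        assert loss.l1_part == 0.0
        assert loss.total == loss.l2_part


class _NaNModel:
    gamma = None

    def train_batch(self, x_t, y, levels, target, l2_only=False):
        return LossValue(total=float("nan"), l2_part=float("nan"), l1_part=0.0)


class TestTrainingStep:
    def test_empty_batch_rejected(self, train_schedule):
        with pytest.raises(ValueError):
            training_step([], _NaNModel(), train_schedule, np.random.default_rng(0))

    def test_non_finite_loss_aborts(self, train_schedule, heavy_pair):
        with pytest.raises(FloatingPointError):
            training_step(
                [heavy_pair], _NaNModel(), train_schedule, np.random.default_rng(0)
            )


class TestSampleRestore:
    def test_oracle_denoiser_is_exact_inverse(self, sampler_schedule, phantom64):
        """With a perfect clean-image oracle the 4-step sampler returns
        the ground truth bit-exactly for every severity and seed."""
        for level in ("minor", "moderate", "heavy"):
            y, _ = corrupt(
                phantom64, MotionConfig.preset(level), np.random.default_rng(3)
            )
            for seed in (0, 1, 12345):
                out = sample_restore(
                    y,
                    ConstantDenoiser(phantom64, gamma=2.0),
                    sampler_schedule,
                    np.random.default_rng(seed),
                )
                assert np.array_equal(out, phantom64)

    def test_oracle_y_fixed_point(self, sampler_schedule, phantom64):
        rng = np.random.default_rng(4)
        y = rng.random((64, 64))
        out = sample_restore(
            y, ConstantDenoiser(y, gamma=2.0), sampler_schedule,
            np.random.default_rng(5),
        )
        assert np.array_equal(out, y)

    def test_denoiser_called_exactly_n_times(self, sampler_schedule, phantom64):
        calls = []

        class CountingOracle(ConstantDenoiser):
            def predict(self, x_t, y, level):
                calls.append(level)
                return super().predict(x_t, y, level)

        sample_restore(
            phantom64,
            CountingOracle(phantom64, gamma=2.0),
            sampler_schedule,
            np.random.default_rng(6),
        )
        assert len(calls) == 4
        # queried at the sampler's own decreasing noise levels
        expected = [noise_level(sampler_schedule, t) for t in (4, 3, 2, 1)]
        assert calls == pytest.approx(expected)

    def test_gamma_mismatch_rejected(self, phantom64):
        other = build_schedule(ScheduleConfig(n_steps=4, gamma=1.0))
        with pytest.raises(ValueError):
            sample_restore(
                phantom64,
                ConstantDenoiser(phantom64, gamma=2.0),
                other,
                np.random.default_rng(0),
            )
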