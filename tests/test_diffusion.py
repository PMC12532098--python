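import numpy as np
import pytest

from mocorr import (
    PairedSample,
    build_schedule,
    forward_marginal,
    forward_step,
    loss,
    posterior_params,
    predict_mean,
    sample,
)
from mocorr.diffusion import TrainConfig


class TestPairedSample:
    def test_residual_derived(self, rng):
        x = rng.random((8, 8))
        y = rng.random((8, 8))
        p = PairedSample(x=x, y=y)
        np.testing.assert_allclose(p.r, y - x, atol=1e-12, rtol=0)

    def test_residual_checked(self, rng):
        x = rng.random((8, 8))
        with pytest.raises(ValueError):
            PairedSample(x=x, y=x, r=x + 1.0)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            PairedSample(x=rng.random((4, 4)), y=rng.random((5, 5)))


class TestForwardStep:
    def test_no_residual_no_noise_identity(self, sched_default, rng):
        x = rng.random((6, 6))
        z = np.zeros_like(x)
        st = forward_step(x, z, sched_default, 2, z)
        np.testing.assert_array_equal(st.x_t, x)

    def test_scalar_hand_case(self):
        # alpha_2 = 0.3 by construction: beta = [0, 0.2, 0.5, ...]
        s = build_schedule(n_steps=2, gamma=2.0, growth_p=1.0, beta1=0.2, betaN=0.5)
        st = forward_step(np.zeros(1), np.ones(1), s, 2, np.ones(1))
        assert st.x_t[0] == pytest.approx(0.3 + 2.0 * np.sqrt(0.3), abs=1e-12)

    def test_chain_telescopes_to_betaN(self, sched_default, rng):
        x = rng.random((10, 10))
        y = rng.random((10, 10))
        r = y - x
        z = np.zeros_like(x)
        cur = x
        for t in range(1, sched_default.n_steps + 1):
            cur = forward_step(cur, r, sched_default, t, z).x_t
        np.testing.assert_allclose(cur, x + 0.999 * r, atol=1e-12, rtol=0)

    def test_shape_mismatch(self, sched_default, rng):
        with pytest.raises(ValueError):
            forward_step(rng.random((4, 4)), rng.random((5, 5)), sched_default, 1,
                         np.zeros((4, 4)))


class TestForwardMarginal:
    def test_zero_residual(self, sched_default, rng):
        x = rng.random((6, 6))
        z = np.zeros_like(x)
        for t in range(sched_default.n_steps + 1):
            np.testing.assert_array_equal(
                forward_marginal(x, x, sched_default, t, z).x_t, x
            )

    def test_t0_exact(self, sched_default, rng):
        x, y = rng.random((6, 6)), rng.random((6, 6))
        st = forward_marginal(x, y, sched_default, 0, np.zeros_like(x))
        np.testing.assert_array_equal(st.x_t, x)

    def test_terminal_close_to_y(self, sched_default, rng):
        x, y = rng.random((6, 6)), rng.random((6, 6))
        st = forward_marginal(x, y, sched_default, 4, np.zeros_like(x))
        np.testing.assert_allclose(st.x_t, x + 0.999 * (y - x), atol=1e-12, rtol=0)

    def test_out_of_range(self, sched_default, rng):
        x = rng.random((4, 4))
        with pytest.raises(ValueError):
            forward_marginal(x, x, sched_default, 5, np.zeros_like(x))

    def test_composition_matches_marginal_mean_and_variance(self, sched_default, rng):
        # mean: iterate steps with zero noise; variance: telescoping of alpha
        x, y = rng.random((9, 9)), rng.random((9, 9))
        r = y - x
        z = np.zeros_like(x)
        cur = x
        for t in range(1, sched_default.n_steps + 1):
            cur = forward_step(cur, r, sched_default, t, z).x_t
            marg = forward_marginal(x, y, sched_default, t, z).x_t
            np.testing.assert_allclose(cur, marg, atol=1e-12, rtol=0)
            var_steps = sched_default.gamma**2 * sched_default.alpha[1 : t + 1].sum()
            var_marg = sched_default.gamma**2 * sched_default.beta[t]
            assert abs(var_steps - var_marg) <= 1e-12

    def test_monte_carlo_moments(self, sched_default):
        # 1e5 scalar draws at t=2; moments within 4 standard errors
        n = 100_000
        t = 2
        x0, y0 = 0.3, 0.9
        rng = np.random.default_rng(777)
        eps = rng.standard_normal(n)
        draws = forward_marginal(
            np.full(n, x0), np.full(n, y0), sched_default, t, eps
        ).x_t
        b = sched_default.beta[t]
        g2b = sched_default.gamma**2 * b
        mean_se = np.sqrt(g2b / n)
        assert abs(draws.mean() - (x0 + b * (y0 - x0))) < 4 * mean_se
        var_se = g2b * np.sqrt(2.0 / (n - 1))
        assert abs(draws.var(ddof=1) - g2b) < 4 * var_se

    def test_vectorized_t(self, sched_default, rng):
        x = rng.random((3, 5, 5))
        y = rng.random((3, 5, 5))
        z = np.zeros_like(x)
        t = np.array([1, 2, 4])
        batched = forward_marginal(x, y, sched_default, t, z).x_t
        for i, ti in enumerate(t):
            single = forward_marginal(x[i], y[i], sched_default, int(ti), z[i]).x_t
            np.testing.assert_array_equal(batched[i], single)


def _grid_posterior_moments(x_t, x, sched, t):
    """Independent oracle: normalize q(x_t|x_{t-1},y) * q(x_{t-1}|x,y) on a
    fine 1-D grid (the y/r terms cancel; see the closed form)."""
    g, bt, btm1, at = sched.gamma, sched.beta[t], sched.beta[t - 1], sched.alpha[t]
    if btm1 == 0.0:
        return x, 0.0
    # grid wide enough to cover both factors
    centre = 0.5 * (x_t + x)
    width = 10.0 * g * (np.sqrt(at) + np.sqrt(btm1)) + abs(x_t - x)
    grid = np.linspace(centre - width, centre + width, 40_001)
    # r-dependent shifts cancel between the two factors, set r = 0
    log_p = -0.5 * (x_t - grid) ** 2 / (g**2 * at) - 0.5 * (grid - x) ** 2 / (
        g**2 * btm1
    )
    w = np.exp(log_p - log_p.max())
    w /= w.sum()
    mean = float((w * grid).sum())
    var = float((w * (grid - mean) ** 2).sum())
    return mean, var


class TestPosterior:
    def test_t1_collapses_to_x(self, sched_default, rng):
        x_t = rng.random((4, 4))
        x = rng.random((4, 4))
        p = posterior_params(x_t, x, sched_default, 1)
        np.testing.assert_array_equal(p.mean, x)
        assert p.variance == 0.0

    def test_scalar_hand_case(self):
        s = build_schedule(n_steps=2, gamma=2.0, growth_p=1.0, beta1=0.2, betaN=0.5)
        # beta_2 = 0.5, beta_1 = 0.2, alpha_2 = 0.3
        p = posterior_params(np.ones(1), np.zeros(1), s, 2)
        assert p.mean[0] == pytest.approx(0.4, abs=1e-12)
        assert p.variance == pytest.approx(4.0 * (0.2 / 0.5) * 0.3, abs=1e-12)

    def test_t0_rejected(self, sched_default, rng):
        x = rng.random((4, 4))
        with pytest.raises(ValueError):
            posterior_params(x, x, sched_default, 0)

    def test_grid_oracle_100_configs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(2, 8))
            sched = build_schedule(
                n_steps=n,
                gamma=float(rng.uniform(0.3, 3.0)),
                growth_p=float(rng.uniform(0.1, 2.0)),
                beta1=float(rng.uniform(1e-4, 0.05)),
                betaN=float(rng.uniform(0.5, 0.999)),
            )
            t = int(rng.integers(2, n + 1))
            x_t = float(rng.normal(0, 1))
            x = float(rng.normal(0, 1))
            p = posterior_params(np.array([x_t]), np.array([x]), sched, t)
            mean_o, var_o = _grid_posterior_moments(x_t, x, sched, t)
            assert abs(p.mean[0] - mean_o) <= 1e-8
            assert abs(p.variance - var_o) <= 1e-8


class TestPredictMean:
    def test_matches_posterior_when_x0hat_is_x(self, sched_default, rng):
        x_t, x = rng.random((5, 5)), rng.random((5, 5))
        for t in range(1, 5):
            a = posterior_params(x_t, x, sched_default, t)
            b = predict_mean(x_t, x, sched_default, t)
            np.testing.assert_array_equal(a.mean, b.mean)
            assert a.variance == b.variance

    def test_t1_returns_x0hat(self, sched_default, rng):
        x_t, x0 = rng.random((5, 5)), rng.random((5, 5))
        p = predict_mean(x_t, x0, sched_default, 1)
        np.testing.assert_array_equal(p.mean, x0)

    def test_scalar_hand_case(self):
        s = build_schedule(n_steps=2, gamma=2.0, growth_p=1.0, beta1=0.2, betaN=0.5)
        p = predict_mean(np.ones(1), 2.0 * np.ones(1), s, 2)
        assert p.mean[0] == pytest.approx(0.4 + 1.2, abs=1e-12)


class TestLoss:
    def test_zero_iff_equal(self, rng):
        x = rng.random((7, 7))
        assert loss(x, x) == 0.0
        y = x.copy()
        y[0, 0] += 1e-3
        assert loss(y, x) > 0.0

    def test_two_pixel_hand_case(self):
        x0_hat = np.array([0.5, 0.5])
        x = np.array([0.0, 0.0])
        assert loss(x0_hat, x) == pytest.approx(0.25 + 0.5, abs=1e-12)
        assert loss(x0_hat, x, mode="l2") == pytest.approx(0.25, abs=1e-12)

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            loss(np.zeros(2), np.zeros(2), mode="huber")

    def test_non_negative_random(self, rng):
        for _ in range(20):
            a, b = rng.normal(size=(2, 6, 6))
            assert loss(a, b) >= 0.0


class TestSampler:
    def test_oracle_denoiser_recovers_x(self, sched_default, rng):
        x = rng.random((12, 12))
        y = rng.random((12, 12))
        for seed in (0, 1, 99):
            out = sample(y, lambda xt, yy, t: x, sched_default, rng_seed=seed)
            np.testing.assert_allclose(out, x, atol=1e-6, rtol=0)

    def test_exactly_n_denoiser_calls(self, sched_default, rng):
        y = rng.random((8, 8))
        calls = []

        def den(xt, yy, t):
            calls.append(t)
            return yy

        sample(y, den, sched_default, rng_seed=0)
        assert calls == [4, 3, 2, 1]

    def test_larger_n(self, rng):
        sched = build_schedule(n_steps=7)
        y = rng.random((8, 8))
        calls = []

        def den(xt, yy, t):
            calls.append(t)
            return yy

        sample(y, den, sched, rng_seed=0)
        assert calls == list(range(7, 0, -1))

    def test_seed_determinism(self, sched_default, rng):
        y = rng.random((8, 8))
        den = lambda xt, yy, t: 0.5 * xt + 0.5 * yy  # noqa: E731
        a = sample(y, den, sched_default, rng_seed=5)
        b = sample(y, den, sched_default, rng_seed=5)
        np.testing.assert_array_equal(a, b)
        c = sample(y, den, sched_default, rng_seed=6)
        assert not np.array_equal(a, c)

    def test_non_finite_y_rejected(self, sched_default):
        y = np.full((4, 4), np.nan)
        with pytest.raises(ValueError):
            sample(y, lambda xt, yy, t: yy, sched_default, rng_seed=0)

    def test_shape_contract_enforced(self, sched_default, rng):
        y = rng.random((8, 8))
        with pytest.raises(ValueError):
            sample(y, lambda xt, yy, t: np.zeros((2, 2)), sched_default, rng_seed=0)


class TestTrainConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(iterations=0)
        with pytest.raises(ValueError):
            TrainConfig(lr_start=1e-4, lr_min=1e-3)
        with pytest.raises(ValueError):
            TrainConfig(loss_mode="l3")
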