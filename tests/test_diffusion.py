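"""DDPM machinery: schedule, forward process, loss, sampler, projection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from diffdecon.autograd import Tensor
from diffdecon.diffusion import (ddpm_sample, forward_noise, make_schedule,
                                 noise_prediction_loss, project_to_simplex,
                                 sample_batch)


class OracleDenoiser:
    """Analytic noise predictor for a known clean target x0*.

    Inverts the closed-form forward marginal: eps = (x_t - sqrt(ab) x0*) /
    sqrt(1 - ab).  Plugged into the ancestral sampler it must steer any
    starting noise back to x0*.
    """

    def __init__(self, x0_star, schedule):
        self.x0 = np.atleast_2d(x0_star)
        self.K = self.x0.shape[1]
        self.schedule = schedule

    def eval(self):
        return self

    def __call__(self, xt, t, c, rng=None):
        ab = self.schedule.alpha_bar[np.asarray(t) - 1][:, None]
        return Tensor((xt - np.sqrt(ab) * self.x0) / np.sqrt(1.0 - ab))


class TestSchedule:
    def test_published_linear_endpoints(self):
        s = make_schedule(T=1000)
        assert s.beta[0] == pytest.approx(1e-4)
        assert s.beta[-1] == pytest.approx(0.02)
        assert np.all(np.diff(s.beta) > 0)

    def test_alpha_bar_equals_explicit_product_loop(self):
        s = make_schedule(T=1000)
        prod = 1.0
        for t in range(1000):
            prod *= 1.0 - s.beta[t]
            assert s.alpha_bar[t] == pytest.approx(prod, rel=1e-12)
        assert np.all(np.diff(s.alpha_bar) < 0)
        assert 0.0 < s.alpha_bar[-1] < 1.0

    def test_single_step_schedule(self):
        s = make_schedule(T=1, beta_start=1e-4, beta_end=1e-4)
        assert s.beta.shape == (1,)
        assert s.alpha_bar[0] == pytest.approx(1.0 - 1e-4)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            make_schedule(T=0)
        with pytest.raises(ValueError):
            make_schedule(beta_start=0.05, beta_end=0.01)
        with pytest.raises(ValueError):
            make_schedule(beta_start=0.0)


class TestForwardNoise:
    def test_zero_noise_scales_by_sqrt_alpha_bar(self):
        s = make_schedule(T=100)
        x0 = np.array([[0.5, 0.5]])
        xt = forward_noise(x0, 50, np.zeros_like(x0), s)
        assert np.allclose(xt, np.sqrt(s.alpha_bar[49]) * x0)

    def test_early_time_near_identity(self):
        s = make_schedule(T=1000)
        x0 = np.array([[0.3, 0.7]])
        eps = np.array([[1.0, -1.0]])
        xt = forward_noise(x0, 1, eps, s)
        assert np.allclose(xt, x0, atol=0.02)

    def test_out_of_range_t_rejected(self):
        s = make_schedule(T=10)
        with pytest.raises(ValueError):
            forward_noise(np.ones((1, 2)), 11, np.zeros((1, 2)), s)
        with pytest.raises(ValueError):
            forward_noise(np.ones((1, 2)), 0, np.zeros((1, 2)), s)

    @pytest.mark.parametrize("t", [1, 100, 1000])
    def test_closed_form_matches_stepwise_markov_chain(self, t):
        """Iterating x_s = sqrt(1-b_s) x_{s-1} + sqrt(b_s) z reproduces the
        closed-form marginal's first two moments within 3 Monte-Carlo SE."""
        s = make_schedule(T=1000)
        rng = np.random.default_rng(10)
        x0 = 0.4
        n = 4000
        x = np.full(n, x0)
        for step in range(t):
            x = (np.sqrt(1 - s.beta[step]) * x
                 + np.sqrt(s.beta[step]) * rng.standard_normal(n))
        mean_expect = np.sqrt(s.alpha_bar[t - 1]) * x0
        var_expect = 1.0 - s.alpha_bar[t - 1]
        se_mean = np.sqrt(var_expect / n)
        assert abs(x.mean() - mean_expect) < 3 * se_mean
        se_var = var_expect * np.sqrt(2.0 / (n - 1))
        assert abs(x.var(ddof=1) - var_expect) < 3 * se_var


class TestLoss:
    def _batch(self):
        rng = np.random.default_rng(0)
        s = make_schedule(T=50)
        x0 = rng.dirichlet(np.ones(3), size=4)
        t = rng.integers(1, 51, 4)
        eps = rng.standard_normal((4, 3))
        xt = forward_noise(x0, t, eps, s)
        c = rng.standard_normal((4, 7))
        return xt, t, c, eps

    def test_exact_denoiser_gives_zero_loss(self):
        xt, t, c, eps = self._batch()
        loss = noise_prediction_loss(lambda *a: Tensor(eps), xt, t, c, eps)
        assert loss.data == pytest.approx(0.0)

    def test_constant_offset_gives_squared_offset(self):
        xt, t, c, eps = self._batch()
        delta = 0.37
        loss = noise_prediction_loss(lambda *a: Tensor(eps + delta),
                                     xt, t, c, eps)
        assert loss.data == pytest.approx(delta ** 2, rel=1e-12)

    def test_matches_hand_computed_mse(self):
        xt, t, c, eps = self._batch()
        rng = np.random.default_rng(1)
        fixed = rng.standard_normal(eps.shape)
        loss = noise_prediction_loss(lambda *a: Tensor(fixed), xt, t, c, eps)
        assert loss.data == pytest.approx(np.mean((fixed - eps) ** 2),
                                          rel=1e-12)

    def test_shape_mismatch_rejected(self):
        xt, t, c, eps = self._batch()
        with pytest.raises(ValueError):
            noise_prediction_loss(lambda *a: Tensor(eps[:, :2]), xt, t, c, eps)


class TestProjectToSimplex:
    def test_on_simplex_unchanged(self):
        x = np.array([0.2, 0.3, 0.5])
        assert np.allclose(project_to_simplex(x), x)

    def test_clip_then_renormalize(self):
        assert np.allclose(project_to_simplex(np.array([-0.1, 0.6, 0.6])),
                           [0.0, 0.5, 0.5])

    def test_all_negative_falls_back_to_uniform(self):
        assert np.allclose(project_to_simplex(np.array([-1.0, -2.0])),
                           [0.5, 0.5])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            project_to_simplex(np.array([np.nan, 1.0]))

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(arrays(np.float64, st.integers(1, 8),
                  elements=st.floats(-1e6, 1e6, allow_nan=False)))
    def test_output_always_valid_proportions(self, x):
        y = project_to_simplex(x)
        assert np.all(y >= 0)
        assert y.sum() == pytest.approx(1.0)
        # already-valid vectors are fixed points
        assert np.allclose(project_to_simplex(y), y)


class TestAncestralSampler:
    def test_oracle_denoiser_recovers_target(self):
        """32-draw average lands within 0.02 L-inf of the known target."""
        s = make_schedule(T=1000)
        x0_star = np.array([0.5, 0.3, 0.15, 0.05])
        oracle = OracleDenoiser(x0_star, s)
        rng = np.random.default_rng(12)
        out = ddpm_sample(oracle, np.zeros(8), s, rng, n_draws=32)
        assert np.max(np.abs(out - x0_star)) < 0.02

    def test_recovery_error_shrinks_with_averaging(self):
        s = make_schedule(T=200)
        x0_star = np.array([0.6, 0.25, 0.15])
        oracle = OracleDenoiser(x0_star, s)

        def err(n_draws, seed):
            rng = np.random.default_rng(seed)
            out = ddpm_sample(oracle, np.zeros(4), s, rng, n_draws=n_draws)
            return np.max(np.abs(out - x0_star))

        e1 = np.mean([err(2, s0) for s0 in range(40, 50)])
        e4 = np.mean([err(8, s0) for s0 in range(50, 60)])
        assert e4 < e1

    def test_zero_denoiser_single_step_algebra(self):
        """With T=1 and eps_hat = 0, output is project(x_1 / sqrt(alpha_1))."""
        s = make_schedule(T=1, beta_start=0.01, beta_end=0.01)
        zero = lambda xt, t, c, rng=None: Tensor(np.zeros_like(xt))
        rng = np.random.default_rng(13)
        out = ddpm_sample(zero, np.zeros(2), s, rng, n_draws=1, K=3)
        x1 = np.random.default_rng(13).standard_normal((1, 3))
        assert np.allclose(out, project_to_simplex(x1[0] / np.sqrt(1 - 0.01)))

    def test_fixed_seed_reproducible(self):
        s = make_schedule(T=50)
        x0_star = np.array([0.7, 0.3])
        oracle = OracleDenoiser(x0_star, s)
        a = ddpm_sample(oracle, np.zeros(2), s, np.random.default_rng(14))
        b = ddpm_sample(oracle, np.zeros(2), s, np.random.default_rng(14))
        assert np.array_equal(a, b)

    def test_batch_rows_independent_of_batch_layout(self):
        """Per-row sub-seeding: a row's sample does not depend on the batch."""
        s = make_schedule(T=30)
        x0_star = np.array([0.5, 0.5])
        oracle = OracleDenoiser(x0_star, s)
        c3 = np.zeros((3, 2))
        full = sample_batch(oracle, c3, s, seed=21)
        # same rows, sampled as a smaller batch with the same master seed
        sub = sample_batch(oracle, c3[:2], s, seed=21)
        assert np.allclose(full[:2], sub)

    def test_sampler_output_on_simplex(self, e2e):
        pred = e2e["diffformer"]["pred"]
        assert np.all(pred >= 0)
        assert np.allclose(pred.sum(axis=1), 1.0, atol=1e-9)
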