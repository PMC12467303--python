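"""DDPM machinery: noise schedule, forward noising, loss, ancestral sampler.

The generative model treats a cell-type proportion vector ``x0`` (a point on
the K-simplex) as the data and a bulk expression profile ``c`` as the
conditioning signal.  The forward process adds Gaussian noise over ``T``
timesteps with per-step variances ``beta_t`` on a linear schedule; a denoiser
network ``eps(x_t, t, c)`` is trained to predict the injected noise, and
ancestral sampling runs the learned reverse chain from pure noise down to a
proportion estimate.

Timesteps are 1-based (``t`` in ``[1, T]``); ``schedule.beta[t-1]`` is the
variance used at step ``t``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .autograd import Tensor, no_grad

__all__ = [
    "NoiseSchedule",
    "make_schedule",
    "forward_noise",
    "noise_prediction_loss",
    "ddpm_sample",
    "project_to_simplex",
]


@dataclass(frozen=True)
class NoiseSchedule:
    """Linear-beta DDPM schedule with derived alpha products.

    Arrays are 0-indexed: entry ``i`` corresponds to timestep ``t = i + 1``.
    """

    T: int
    beta: np.ndarray        # beta_t, shape (T,)
    alpha: np.ndarray       # 1 - beta_t
    alpha_bar: np.ndarray   # cumulative product of alpha up to t

    def __post_init__(self):
        if self.beta.shape != (self.T,):
            raise ValueError("beta length must equal T")


def make_schedule(T: int = 1000, beta_start: float = 1e-4,
                  beta_end: float = 0.02) -> NoiseSchedule:
    """Linearly spaced betas inclusive of both endpoints."""
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    if not (0.0 < beta_start <= beta_end < 1.0):
        raise ValueError(
            f"need 0 < beta_start <= beta_end < 1, got ({beta_start}, {beta_end})")
    beta = np.linspace(beta_start, beta_end, T)
    alpha = 1.0 - beta
    alpha_bar = np.cumprod(alpha)
    return NoiseSchedule(T=T, beta=beta, alpha=alpha, alpha_bar=alpha_bar)


def _check_t(t: np.ndarray | int, T: int) -> np.ndarray:
    t = np.atleast_1d(np.asarray(t, dtype=np.int64))
    if np.any(t < 1) or np.any(t > T):
        raise ValueError(f"timesteps must lie in [1, {T}]")
    return t


def forward_noise(x0: np.ndarray, t: np.ndarray | int, eps: np.ndarray,
                  schedule: NoiseSchedule) -> np.ndarray:
    """Closed-form forward marginal: ``sqrt(ab_t) x0 + sqrt(1-ab_t) eps``."""
    x0 = np.asarray(x0, dtype=np.float64)
    eps = np.asarray(eps, dtype=np.float64)
    if eps.shape != x0.shape:
        raise ValueError(f"eps shape {eps.shape} != x0 shape {x0.shape}")
    t = _check_t(t, schedule.T)
    ab = schedule.alpha_bar[t - 1]
    if x0.ndim == 2:
        ab = ab[:, None] if ab.size > 1 else ab
    return np.sqrt(ab) * x0 + np.sqrt(1.0 - ab) * eps


def noise_prediction_loss(denoiser: Callable[..., Tensor], xt: np.ndarray,
                          t: np.ndarray, c: np.ndarray, eps: np.ndarray,
                          rng: np.random.Generator | None = None) -> Tensor:
    """Mean squared error between true and predicted noise.

    ``denoiser(xt, t, c, rng)`` must return a Tensor of eps's shape; the mean
    is taken over both the batch and the proportion components.
    """
    pred = denoiser(xt, t, c, rng)
    if pred.shape != eps.shape:
        raise ValueError(f"denoiser output {pred.shape} != eps {eps.shape}")
    diff = pred - Tensor(eps)
    return (diff * diff).mean()


def project_to_simplex(x: np.ndarray) -> np.ndarray:
    """Clip negatives to zero and renormalize rows to sum one.

    Rows that are entirely non-positive fall back to the uniform vector, so
    the output is always a valid proportion vector.  Clipping (rather than a
    softmax) preserves exact zeros for absent cell types.
    """
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in simplex projection input")
    squeeze = x.ndim == 1
    x = np.atleast_2d(x)
    y = np.clip(x, 0.0, None)
    s = y.sum(axis=1, keepdims=True)
    zero = (s[:, 0] == 0.0)
    y[zero] = 1.0 / x.shape[1]
    s[zero] = 1.0
    y = y / s
    return y[0] if squeeze else y


def _reverse_chain(denoiser, x: np.ndarray, c: np.ndarray,
                   schedule: NoiseSchedule,
                   rngs: Sequence[np.random.Generator],
                   variance: str = "beta") -> np.ndarray:
    """One full ancestral pass from x_T down to x_0 (batched over rows).

    Reverse-process variance is ``sigma_t^2 = beta_t`` by default
    (``variance="posterior"`` uses the smaller beta-tilde variant); the
    injected noise at each step is drawn per row from that row's generator
    so a row's result does not depend on which other rows share the batch.
    """
    if variance not in ("beta", "posterior"):
        raise ValueError(f"unknown variance choice {variance!r}")
    n, k = x.shape
    for t in range(schedule.T, 0, -1):
        beta = schedule.beta[t - 1]
        alpha = schedule.alpha[t - 1]
        ab = schedule.alpha_bar[t - 1]
        with no_grad():
            eps_hat = denoiser(x, np.full(n, t, dtype=np.int64), c, None)
        eps_hat = eps_hat.data if isinstance(eps_hat, Tensor) else np.asarray(eps_hat)
        x = (x - (beta / np.sqrt(1.0 - ab)) * eps_hat) / np.sqrt(alpha)
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(f"non-finite state at timestep {t}")
        if t > 1:
            sigma2 = beta
            if variance == "posterior":
                sigma2 = beta * (1.0 - schedule.alpha_bar[t - 2]) / (1.0 - ab)
            z = np.stack([r.standard_normal(k) for r in rngs])
            x = x + np.sqrt(sigma2) * z
    return x


def ddpm_sample(denoiser, c: np.ndarray, schedule: NoiseSchedule,
                rng: np.random.Generator, n_draws: int = 1,
                K: int | None = None, variance: str = "beta") -> np.ndarray:
    """Sample a proportion vector for a single bulk profile ``c``.

    Runs ``n_draws`` independent reverse chains, averages them, and projects
    the average onto the simplex.  ``K`` defaults to the denoiser's output
    dimension if it exposes one.
    """
    c = np.asarray(c, dtype=np.float64)
    if c.ndim != 1:
        raise ValueError("c must be a single profile (1-D)")
    if K is None:
        K = getattr(denoiser, "K", None)
        if K is None:
            raise ValueError("pass K explicitly for denoisers without a K attribute")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    acc = np.zeros(K)
    for _ in range(n_draws):
        x = rng.standard_normal((1, K))
        x0 = _reverse_chain(denoiser, x, c[None, :], schedule, [rng], variance)
        acc += x0[0]
    return project_to_simplex(acc / n_draws)


def sample_batch(denoiser, c: np.ndarray, schedule: NoiseSchedule,
                 seed: int, n_draws: int = 1, K: int | None = None,
                 variance: str = "beta") -> np.ndarray:
    """Batched ancestral sampling with a per-row derived sub-seed.

    Each row's noise stream comes from ``SeedSequence(seed).spawn(N)[i]``, so
    the estimate for a sample is reproducible regardless of batch layout.
    """
    c = np.atleast_2d(np.asarray(c, dtype=np.float64))
    n = c.shape[0]
    if K is None:
        K = getattr(denoiser, "K")
    if n == 0:
        return np.zeros((0, K))
    rngs = [np.random.Generator(np.random.PCG64(s))
            for s in np.random.SeedSequence(seed).spawn(n)]
    acc = np.zeros((n, K))
    for _ in range(n_draws):
        x = np.stack([r.standard_normal(K) for r in rngs])
        acc += _reverse_chain(denoiser, x, c, schedule, rngs, variance)
    return project_to_simplex(acc / n_draws)
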