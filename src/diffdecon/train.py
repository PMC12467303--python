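"""Seeded training loop: AdamW, cosine LR annealing, early stopping.

Each step draws a batch, samples timesteps uniformly on [1, T], injects the
corresponding closed-form forward noise and minimizes the noise-prediction
MSE.  Early stopping monitors a held-out validation split whose noise
realization is frozen at split time, so the stopping signal is a
low-variance function of the parameters rather than of fresh noise draws.
Best-validation parameters (ties to the earlier epoch) are returned.

All randomness — split shuffle, parameter init, batch order, timestep and
noise draws, dropout masks — descends from the single training seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import no_grad
from .diffusion import NoiseSchedule, forward_noise, noise_prediction_loss, sample_batch
from .models import build_denoiser, set_conditioning_stats
from .nn import Module

__all__ = ["TrainingConfig", "TrainingTrace", "AdamW", "cosine_lr",
           "train_model", "infer_proportions"]


@dataclass(frozen=True)
class TrainingConfig:
    lr: float = 1e-4
    weight_decay: float = 0.01
    adam_betas: tuple[float, float] = (0.9, 0.999)
    adam_eps: float = 1e-8
    epochs: int = 150
    batch_size: int = 64
    t_max: int = 150                # cosine annealing period, in epochs
    eta_min: float = 1e-6
    early_stop_patience: int = 20
    val_fraction: float = 0.1
    seed: int = 42

    def __post_init__(self):
        if min(self.lr, self.adam_eps, self.epochs, self.batch_size) <= 0:
            raise ValueError("lr, adam_eps, epochs, batch_size must be positive")
        if self.early_stop_patience < 1:
            raise ValueError("early_stop_patience must be >= 1")
        if self.early_stop_patience > self.epochs:
            raise ValueError("patience must not exceed epochs")
        if not 0.0 < self.val_fraction <= 0.5:
            raise ValueError("val_fraction must be in (0, 0.5]")


@dataclass
class TrainingTrace:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stop_reason: str = ""


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params, lr: float, weight_decay: float,
                 betas: tuple[float, float], eps: float):
        self.params = list(params)
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def cosine_lr(epoch: int, lr: float, eta_min: float, t_max: int) -> float:
    """Cosine annealing: ``lr`` at epoch 0 down to ``eta_min`` at ``t_max``."""
    if t_max <= 0:
        return lr
    frac = min(epoch, t_max) / t_max
    return eta_min + 0.5 * (lr - eta_min) * (1 + np.cos(np.pi * frac))


def train_model(kind: str, train_bulk: np.ndarray, train_props: np.ndarray,
                config: TrainingConfig, schedule: NoiseSchedule,
                model_overrides: dict | None = None
                ) -> tuple[Module, TrainingTrace]:
    """Train a denoiser (``"diffformer"`` or ``"diffmlp"``) on pseudo-bulk data.

    Returns the model loaded with its best-validation parameters and the
    per-epoch trace.
    """
    n, K = train_props.shape
    G = train_bulk.shape[1]
    if train_bulk.shape[0] != n or n == 0:
        raise ValueError("empty or inconsistent training set")
    ss = np.random.SeedSequence(config.seed)
    s_split, s_init, s_loop = ss.spawn(3)
    rng_split = np.random.Generator(np.random.PCG64(s_split))
    rng = np.random.Generator(np.random.PCG64(s_loop))

    # held-out validation split with a frozen noise realization
    perm = rng_split.permutation(n)
    n_val = max(1, int(round(config.val_fraction * n)))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if tr_idx.size == 0:
        raise ValueError("validation split leaves no training samples")
    val_x0, val_c = train_props[val_idx], train_bulk[val_idx]
    val_t = rng_split.integers(1, schedule.T + 1, size=n_val)
    val_eps = rng_split.standard_normal(val_x0.shape)
    val_xt = forward_noise(val_x0, val_t, val_eps, schedule)

    model = build_denoiser(kind, K=K, G=G, T=schedule.T,
                           seed=int(s_init.generate_state(1)[0] % (2 ** 31)),
                           **(model_overrides or {}))
    # bulk-token standardization from the training portion only
    set_conditioning_stats(model, train_bulk[tr_idx].mean(axis=0),
                           train_bulk[tr_idx].std(axis=0) + 1e-8)
    opt = AdamW(model.parameters(), config.lr, config.weight_decay,
                config.adam_betas, config.adam_eps)
    t_max = config.t_max

    trace = TrainingTrace()
    best_val = np.inf
    best_state: list[np.ndarray] | None = None
    since_best = 0
    for epoch in range(config.epochs):
        opt.lr = cosine_lr(epoch, config.lr, config.eta_min, t_max)
        model.train()
        order = rng.permutation(tr_idx.size)
        losses = []
        for start in range(0, tr_idx.size, config.batch_size):
            rows = tr_idx[order[start:start + config.batch_size]]
            x0, c = train_props[rows], train_bulk[rows]
            t = rng.integers(1, schedule.T + 1, size=rows.size)
            eps = rng.standard_normal(x0.shape)
            xt = forward_noise(x0, t, eps, schedule)
            loss = noise_prediction_loss(model, xt, t, c, eps, rng)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch row {start}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        model.eval()
        with no_grad():
            vloss = float(noise_prediction_loss(
                model, val_xt, val_t, val_c, val_eps).data)
        trace.train_loss.append(float(np.mean(losses)))
        trace.val_loss.append(vloss)
        trace.lr.append(opt.lr)
        if vloss < best_val:
            best_val = vloss
            best_state = [p.copy() for p in model.state_arrays()]
            trace.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.early_stop_patience:
                trace.stop_reason = f"early stop at epoch {epoch}"
                break
    else:
        trace.stop_reason = "completed all epochs"
    model.load_state_arrays(best_state)
    model.eval()
    return model, trace


def infer_proportions(model: Module, bulk: np.ndarray, schedule: NoiseSchedule,
                      seed: int, n_draws: int = 1,
                      hvg_ids: list[str] | None = None,
                      expected_hvg_ids: list[str] | None = None) -> np.ndarray:
    """Row-wise conditional sampling of proportions for a bulk matrix.

    If both ``hvg_ids`` (the columns of ``bulk``) and ``expected_hvg_ids``
    (the checkpoint's gene order) are given, they must match exactly.
    """
    bulk = np.atleast_2d(np.asarray(bulk, dtype=np.float64))
    if hvg_ids is not None and expected_hvg_ids is not None:
        if list(hvg_ids) != list(expected_hvg_ids):
            mism = [(i, a, b) for i, (a, b)
                    in enumerate(zip(hvg_ids, expected_hvg_ids)) if a != b][:5]
            raise ValueError(f"gene order mismatch vs checkpoint; first diffs {mism}")
    model.eval()
    return sample_batch(model, bulk, schedule, seed=seed, n_draws=n_draws)
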