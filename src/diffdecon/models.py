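"""Denoiser networks: the Transformer token-fusion model and an MLP baseline.

Both networks predict the Gaussian noise injected into a proportion vector,
given the noisy vector ``x_t``, the timestep ``t`` and the conditioning bulk
profile ``c``.  They differ only in how the three input modalities are fused:

* :class:`DiffFormer` embeds each modality to ``d_model``, arranges the three
  embeddings as the token sequence ``[proportion, time, bulk]`` with learnable
  positional embeddings, runs a pre-norm Transformer encoder over them and
  projects the first token back to K dimensions (no output activation, so the
  full real line is available for noise prediction).
* :class:`DiffMLP` concatenates the same three embeddings and pushes them
  through a plain MLP — the ablation baseline showing that attention-based
  fusion, not the diffusion framework alone, carries the performance.

The timestep enters both models as the scaled scalar ``t / T`` before its
1-to-d_model affine embedding; raw step indices in the hundreds destabilize
training.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .autograd import Tensor, stack, concat
from .nn import Dropout, LayerNorm, Linear, Module, Parameter, TransformerEncoderLayer

__all__ = ["DenoiserConfig", "MLPDenoiserConfig", "DiffFormer", "DiffMLP",
           "build_denoiser", "set_conditioning_stats", "conditioning_stats"]


@dataclass(frozen=True)
class DenoiserConfig:
    """Transformer denoiser hyperparameters (defaults as published)."""

    K: int
    G: int
    d_model: int = 128
    n_heads: int = 4
    n_layers: int = 3
    d_ff: int = 256
    dropout: float = 0.1
    T: int = 1000  # timestep normalizer for the t/T embedding

    def __post_init__(self):
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.G < 1:
            raise ValueError("G must be >= 1")
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass(frozen=True)
class MLPDenoiserConfig:
    """MLP baseline: same embeddings, concatenation fusion, hidden stack."""

    K: int
    G: int
    d_model: int = 128
    hidden: tuple[int, ...] = (256, 256)
    dropout: float = 0.1
    T: int = 1000

    def __post_init__(self):
        if self.K < 2 or self.G < 1:
            raise ValueError("K must be >= 2 and G >= 1")
        if any(h < 1 for h in self.hidden):
            raise ValueError("hidden widths must be positive")


class _Embeddings(Module):
    """The three per-modality affine embeddings shared by both denoisers.

    The bulk profile is standardized per gene with training-set statistics
    (``cond_mean``/``cond_std`` buffers, identity until set) before its
    affine embedding: log-normalized expression values span an order of
    magnitude across genes, and without standardization the denoiser
    effectively ignores the conditioning token.
    """

    def __init__(self, K: int, G: int, d_model: int, T: int,
                 rng: np.random.Generator):
        super().__init__()
        self.T = T
        self.prop_embed = Linear(K, d_model, rng)
        self.time_embed = Linear(1, d_model, rng)
        self.bulk_embed = Linear(G, d_model, rng)
        self.cond_mean = np.zeros(G)
        self.cond_std = np.ones(G)

    def __call__(self, xt, t, c) -> tuple[Tensor, Tensor, Tensor]:
        xt = Tensor(np.atleast_2d(xt))
        c = np.atleast_2d(np.asarray(c, dtype=np.float64))
        c = Tensor((c - self.cond_mean) / self.cond_std)
        ts = np.atleast_1d(np.asarray(t, dtype=np.float64))[:, None] / self.T
        return (self.prop_embed(xt), self.time_embed(Tensor(ts)),
                self.bulk_embed(c))


class DiffFormer(Module):
    """Transformer-encoder denoiser with three-token modality fusion."""

    def __init__(self, config: DenoiserConfig, seed: int = 0):
        super().__init__()
        rng = np.random.Generator(np.random.PCG64(seed))
        self.config = config
        self.K = config.K
        self.embed = _Embeddings(config.K, config.G, config.d_model, config.T, rng)
        self.pos_embed = Parameter(rng.normal(0.0, 0.02, size=(3, config.d_model)))
        self.layers = [
            TransformerEncoderLayer(config.d_model, config.n_heads,
                                    config.d_ff, config.dropout, rng)
            for _ in range(config.n_layers)
        ]
        self.final_ln = LayerNorm(config.d_model)
        self.out_proj = Linear(config.d_model, config.K, rng)

    def embed_tokens(self, xt, t, c) -> Tensor:
        """(batch, 3, d_model) token sequence [proportion, time, bulk]."""
        p_tok, t_tok, c_tok = self.embed(xt, t, c)
        return stack([p_tok, t_tok, c_tok], axis=1) + self.pos_embed

    def __call__(self, xt, t, c, rng: np.random.Generator | None = None) -> Tensor:
        h = self.embed_tokens(xt, t, c)
        for layer in self.layers:
            h = layer(h, rng)
        h = self.final_ln(h)
        out = self.out_proj(h[:, 0, :])
        if not np.all(np.isfinite(out.data)):
            raise FloatingPointError("non-finite denoiser output")
        return out


class DiffMLP(Module):
    """Concatenation-fusion MLP denoiser (ablation baseline)."""

    def __init__(self, config: MLPDenoiserConfig, seed: int = 0):
        super().__init__()
        rng = np.random.Generator(np.random.PCG64(seed))
        self.config = config
        self.K = config.K
        self.embed = _Embeddings(config.K, config.G, config.d_model, config.T, rng)
        self.hidden_layers = []
        d_in = 3 * config.d_model
        for width in config.hidden:
            self.hidden_layers.append(Linear(d_in, width, rng))
            d_in = width
        self.drop = Dropout(config.dropout)
        self.out_proj = Linear(d_in, config.K, rng)

    def __call__(self, xt, t, c, rng: np.random.Generator | None = None) -> Tensor:
        p_tok, t_tok, c_tok = self.embed(xt, t, c)
        h = concat([p_tok, t_tok, c_tok], axis=-1)
        for layer in self.hidden_layers:
            h = self.drop(layer(h).gelu(), rng)
        out = self.out_proj(h)
        if not np.all(np.isfinite(out.data)):
            raise FloatingPointError("non-finite denoiser output")
        return out


def set_conditioning_stats(model: Module, mean: np.ndarray,
                           std: np.ndarray) -> None:
    """Install per-gene standardization buffers for the bulk token."""
    std = np.asarray(std, dtype=np.float64)
    if np.any(std <= 0):
        raise ValueError("conditioning std must be positive")
    model.embed.cond_mean = np.asarray(mean, dtype=np.float64).copy()
    model.embed.cond_std = std.copy()


def conditioning_stats(model: Module) -> tuple[np.ndarray, np.ndarray]:
    return model.embed.cond_mean, model.embed.cond_std


def build_denoiser(kind: str, K: int, G: int, T: int, seed: int = 0,
                   **overrides) -> Module:
    """Construct a denoiser by name (``"diffformer"`` or ``"diffmlp"``)."""
    kind = kind.lower()
    if kind == "diffformer":
        return DiffFormer(DenoiserConfig(K=K, G=G, T=T, **overrides), seed=seed)
    if kind == "diffmlp":
        return DiffMLP(MLPDenoiserConfig(K=K, G=G, T=T, **overrides), seed=seed)
    raise ValueError(f"unknown denoiser kind {kind!r}")


def config_to_dict(model: Module) -> dict:
    d = asdict(model.config)
    d["kind"] = "diffformer" if isinstance(model, DiffFormer) else "diffmlp"
    if "hidden" in d:
        d["hidden"] = list(d["hidden"])
    return d


def denoiser_from_dict(d: dict, seed: int = 0) -> Module:
    d = dict(d)
    kind = d.pop("kind")
    if kind == "diffformer":
        return DiffFormer(DenoiserConfig(**d), seed=seed)
    if kind == "diffmlp":
        d["hidden"] = tuple(d["hidden"])
        return DiffMLP(MLPDenoiserConfig(**d), seed=seed)
    raise ValueError(f"unknown denoiser kind {kind!r}")
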