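"""Neural-network layers built on :mod:`diffdecon.autograd`.

Provides the building blocks for the denoiser networks: linear layers,
affine layer normalization, dropout, multi-head self-attention and the
pre-norm Transformer encoder layer.  Initialization is seed-controlled and
follows the usual fan-in (Xavier/Glorot) schemes.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)
        # parameters must stay trainable even if created under no_grad
        self.requires_grad = True


class Module:
    """Lightweight module base: parameter collection and train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def train(self) -> "Module":
        self.training = True
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v.train()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.train()
        return self

    def eval(self) -> "Module":
        self.train()  # set flags recursively, then flip
        self._set_eval()
        return self

    def _set_eval(self) -> None:
        self.training = False
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v._set_eval()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item._set_eval()

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"checkpoint holds {len(arrays)} arrays, model has {len(params)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float64).copy()


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        bound = np.sqrt(6.0 / (d_in + d_out))
        self.weight = Parameter(rng.uniform(-bound, bound, size=(d_in, d_out)))
        self.bias = Parameter(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(d))
        self.beta = Parameter(np.zeros(d))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return x.layer_norm(self.eps) * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; identity in eval mode.

    The mask RNG is supplied per call so that training remains a pure
    function of the training seed.
    """

    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an RNG")
        mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class MultiHeadSelfAttention(Module):
    """Softmax self-attention with dropout on the attention weights."""

    def __init__(self, d_model: int, n_heads: int, dropout: float,
                 rng: np.random.Generator):
        super().__init__()
        if d_model % n_heads != 0:
            raise ValueError(f"d_model={d_model} not divisible by n_heads={n_heads}")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.q_proj = Linear(d_model, d_model, rng)
        self.k_proj = Linear(d_model, d_model, rng)
        self.v_proj = Linear(d_model, d_model, rng)
        self.out_proj = Linear(d_model, d_model, rng)
        self.attn_drop = Dropout(dropout)

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        b, s, d = x.shape
        h, dh = self.n_heads, self.d_head

        def split_heads(t: Tensor) -> Tensor:
            return t.reshape(b, s, h, dh).transpose(0, 2, 1, 3)

        q = split_heads(self.q_proj(x))
        k = split_heads(self.k_proj(x))
        v = split_heads(self.v_proj(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        attn = scores.softmax(axis=-1)
        attn = self.attn_drop(attn, rng)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(b, s, d)
        return self.out_proj(ctx)


class TransformerEncoderLayer(Module):
    """Pre-norm encoder block: x + Attn(LN(x)), then x + FF(LN(x)).

    Dropout is applied to the attention weights and inside the feed-forward
    network (after the activation), matching the denoiser description.
    """

    def __init__(self, d_model: int, n_heads: int, d_ff: int, dropout: float,
                 rng: np.random.Generator):
        super().__init__()
        self.ln1 = LayerNorm(d_model)
        self.attn = MultiHeadSelfAttention(d_model, n_heads, dropout, rng)
        self.ln2 = LayerNorm(d_model)
        self.ff1 = Linear(d_model, d_ff, rng)
        self.ff2 = Linear(d_ff, d_model, rng)
        self.ff_drop = Dropout(dropout)

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        x = x + self.attn(self.ln1(x), rng)
        h = self.ff_drop(self.ff1(self.ln2(x)).gelu(), rng)
        return x + self.ff2(h)
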