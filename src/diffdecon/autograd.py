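"""Minimal reverse-mode automatic differentiation on numpy arrays.

The denoiser networks in this package are small (three tokens, a few hundred
thousand parameters) and run on CPU, so a compact tape-based engine is all
that is needed: a :class:`Tensor` wraps an ``ndarray``, records the operations
applied to it, and :meth:`Tensor.backward` walks the tape in reverse
topological order accumulating gradients.  Broadcasting follows numpy rules;
gradients of broadcast operands are summed back to the operand's shape.

Gradient tracking can be suspended with :func:`no_grad` (used during
inference/sampling where the graph would only waste memory).
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable

import numpy as np
from scipy.special import erf

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager that disables graph construction."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were size 1 in the original shape
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple["Tensor", ...] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self.grad: np.ndarray | None = None
        self._parents = parents if self.requires_grad else ()
        self._backward = backward

    # ---- construction helpers -------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # ---- graph machinery -------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            grad = np.ones_like(self.data)
        # topological order by depth-first search
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # ---- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_req = self.requires_grad or other.requires_grad
        out = Tensor(self.data + other.data, out_req, (self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g, self.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(g, other.shape))
            out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_req = self.requires_grad or other.requires_grad
        out = Tensor(self.data * other.data, out_req, (self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g * other.data, self.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(g * self.data, other.shape))
            out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_req = self.requires_grad or other.requires_grad
        out = Tensor(self.data / other.data, out_req, (self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g / other.data, self.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(-g * self.data / other.data ** 2,
                                              other.shape))
            out._backward = bw
        return out

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(
                g * exponent * self.data ** (exponent - 1))
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out_req = self.requires_grad or other.requires_grad
        out = Tensor(self.data @ other.data, out_req, (self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    ga = g @ np.swapaxes(other.data, -1, -2)
                    self._accum(_unbroadcast(ga, self.shape))
                if other.requires_grad:
                    gb = np.swapaxes(self.data, -1, -2) @ g
                    other._accum(_unbroadcast(gb, other.shape))
            out._backward = bw
        return out

    # ---- shape ops -------------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g.reshape(self.shape))
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes), self.requires_grad, (self,))
        if out.requires_grad:
            inv = np.argsort(axes)
            out._backward = lambda g: self._accum(g.transpose(*inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))
        if out.requires_grad:
            def bw(g):
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)
            out._backward = bw
        return out

    # ---- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))
        if out.requires_grad:
            def bw(g):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.shape).copy())
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ---- nonlinearities --------------------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * out.data)
        return out

    def gelu(self):
        """Exact (erf-based) Gaussian error linear unit."""
        x = self.data
        phi = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        out = Tensor(x * phi, self.requires_grad, (self,))
        if out.requires_grad:
            pdf = np.exp(-0.5 * x ** 2) / np.sqrt(2.0 * np.pi)
            out._backward = lambda g: self._accum(g * (phi + x * pdf))
        return out

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, self.requires_grad, (self,))
        if out.requires_grad:
            def bw(g):
                dot = (g * s).sum(axis=axis, keepdims=True)
                self._accum(s * (g - dot))
            out._backward = bw
        return out

    def layer_norm(self, eps: float = 1e-5):
        """Normalize over the last axis to zero mean / unit variance."""
        x = self.data
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc ** 2).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        y = xc * inv
        out = Tensor(y, self.requires_grad, (self,))
        if out.requires_grad:
            n = x.shape[-1]

            def bw(g):
                gy = g
                gx = inv * (gy - gy.mean(axis=-1, keepdims=True)
                            - y * (gy * y).mean(axis=-1, keepdims=True))
                self._accum(gx)
            out._backward = bw
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    """Stack tensors along a new axis (differentiable)."""
    tensors = list(tensors)
    req = any(t.requires_grad for t in tensors)
    out = Tensor(np.stack([t.data for t in tensors], axis=axis),
                 req, tuple(tensors))
    if out.requires_grad:
        def bw(g):
            parts = np.split(g, len(tensors), axis=axis)
            for t, p in zip(tensors, parts):
                if t.requires_grad:
                    t._accum(np.squeeze(p, axis=axis))
        out._backward = bw
    return out


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along an existing axis (differentiable)."""
    tensors = list(tensors)
    req = any(t.requires_grad for t in tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 req, tuple(tensors))
    if out.requires_grad:
        sizes = [t.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def bw(g):
            parts = np.split(g, splits, axis=axis)
            for t, p in zip(tensors, parts):
                if t.requires_grad:
                    t._accum(p)
        out._backward = bw
    return out
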