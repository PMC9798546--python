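"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This is the package's compute engine: a small tape-based autodiff with the
handful of differentiable operations the attention model needs (broadcasting
arithmetic, batched matmul, softmax with additive masking, layer norm
building blocks). Gradients are accumulated by topological traversal of the
operation graph. Correctness is pinned against central finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "masked_softmax", "layer_norm", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    # -- graph bookkeeping -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.data.shape),
                    _unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data * other.data

        def backward(g):
            return (_unbroadcast(g * other.data, self.data.shape),
                    _unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data / other.data

        def backward(g):
            return (_unbroadcast(g / other.data, self.data.shape),
                    _unbroadcast(-g * self.data / other.data ** 2,
                                 other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    def __matmul__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data @ other.data

        def backward(g):
            a, b = self.data, other.data
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            if a.ndim == 1:  # vector @ matrix
                ga = (g[..., None, :] @ np.swapaxes(b, -1, -2)).reshape(a.shape)
                gb = a[:, None] * g
            return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))

        return Tensor._make(out_data, (self, other), backward)

    def pow(self, exponent: float):
        out_data = self.data ** exponent

        def backward(g):
            return (g * exponent * self.data ** (exponent - 1),)

        return Tensor._make(out_data, (self,), backward)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        old = self.data.shape
        return Tensor._make(self.data.reshape(*shape), (self,),
                            lambda g: (g.reshape(old),))

    def transpose(self, *axes):
        inv = np.argsort(axes)
        return Tensor._make(self.data.transpose(axes), (self,),
                            lambda g: (g.transpose(inv),))

    def swap_last(self):
        return Tensor._make(np.swapaxes(self.data, -1, -2), (self,),
                            lambda g: (np.swapaxes(g, -1, -2),))

    # -- nonlinearities ----------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,),
                            lambda g: (g / self.data,))

    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(out_data, (self,),
                            lambda g: (g * out_data * (1.0 - out_data),))

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through unsaturated entries only."""
        inside = (self.data >= lo) & (self.data <= hi)
        return Tensor._make(np.clip(self.data, lo, hi), (self,),
                            lambda g: (g * inside,))

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, shape).copy(),)
            if not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, shape).copy(),)

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- backprop ------------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is None:
                continue
            grads = t._backward(t.grad)
            for parent, g in zip(t._parents, grads):
                if parent.requires_grad:
                    if parent.grad is None:
                        parent.grad = np.zeros_like(parent.data)
                    parent.grad += g


def concat(tensors: list, axis: int) -> Tensor:
    """Concatenate tensors along an axis."""
    data = np.concatenate([t.data for t in tensors], axis=axis)
    splits = np.cumsum([t.data.shape[axis] for t in tensors])[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(data, tuple(tensors), backward)


def masked_softmax(logits: Tensor, key_mask: np.ndarray) -> Tensor:
    """Softmax over the last axis restricted to positions where key_mask == 1.

    Masked positions receive probability exactly 0; rows are normalized over
    the unmasked positions. `key_mask` is broadcastable to `logits` and is a
    constant (no gradient flows into it).
    """
    mask = np.broadcast_to(np.asarray(key_mask, dtype=bool), logits.data.shape)
    neg = np.where(mask, 0.0, -np.inf)
    shifted = logits.data + neg
    m = np.max(shifted, axis=-1, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)  # all-masked rows stay finite
    e = np.exp(shifted - m)
    z = e.sum(axis=-1, keepdims=True)
    out_data = np.where(z > 0, e / np.where(z > 0, z, 1.0), 0.0)

    def backward(g):
        s = out_data
        dot = (g * s).sum(axis=-1, keepdims=True)
        return ((g - dot) * s,)

    return Tensor._make(out_data, (logits,), backward)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor,
               eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis with learnable gain/bias."""
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = centered.pow(2).mean(axis=-1, keepdims=True)
    inv = (var + eps).pow(-0.5)
    return centered * inv * gain + bias


class Adam:
    """Adam optimizer over a dict of named parameter Tensors."""

    def __init__(self, params: dict, lr: float = 7e-5, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None
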