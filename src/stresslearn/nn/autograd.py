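"""Minimal reverse-mode automatic differentiation on numpy arrays.

The models in this package are small (a one-layer LSTM autoencoder plus a
handful of fully connected heads), so a compact tape-based autograd engine
is sufficient: a :class:`Tensor` wraps an ndarray, records its parents and
a backward closure, and :meth:`Tensor.backward` walks the tape in reverse
topological order.  Only the operations the models need are implemented.

Gradients accumulate into ``.grad``; broadcasting in elementwise ops is
undone by summing over broadcast axes before accumulation.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "softmax",
    "cross_entropy",
    "take_columns",
    "take_rows",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph machinery ----------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (scalar unless ``grad`` given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ---------------------------------------------------------
    def _binary(self, other, fwd, bwd_self, bwd_other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = fwd(self.data, other.data)
        req = self.requires_grad or other.requires_grad
        out = Tensor(out_data, requires_grad=req, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(bwd_self(g, self.data, other.data), self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(bwd_other(g, self.data, other.data), other.data.shape))

        out._backward = backward if req else None
        return out

    def __add__(self, other):
        return self._binary(other, lambda a, b: a + b, lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(other, lambda a, b: a - b, lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, other):
        return Tensor(other) - self

    def __mul__(self, other):
        return self._binary(other, lambda a, b: a * b, lambda g, a, b: g * b, lambda g, a, b: g * a)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self._binary(
            other,
            lambda a, b: a / b,
            lambda g, a, b: g / b,
            lambda g, a, b: -g * a / (b * b),
        )

    def __neg__(self):
        return self * -1.0

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data @ other.data, requires_grad=self.requires_grad or other.requires_grad,
                     parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out._backward = backward if out.requires_grad else None
        return out

    # -- elementwise nonlinearities ----------------------------------------
    def _unary(self, fwd_data, bwd) -> "Tensor":
        out = Tensor(fwd_data, requires_grad=self.requires_grad, parents=(self,))

        def backward(g):
            self._accumulate(bwd(g, out.data))

        out._backward = backward if self.requires_grad else None
        return out

    def relu(self):
        return self._unary(np.maximum(self.data, 0.0), lambda g, y: g * (y > 0))

    def tanh(self):
        return self._unary(np.tanh(self.data), lambda g, y: g * (1.0 - y * y))

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        return self._unary(y, lambda g, y: g * y * (1.0 - y))

    def abs(self):
        sign = np.sign(self.data)
        return self._unary(np.abs(self.data), lambda g, y, s=sign: g * s)

    # -- reductions and reshaping -------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        out = Tensor(out_data, requires_grad=self.requires_grad, parents=(self,))

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = backward if self.requires_grad else None
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        orig = self.data.shape
        out = Tensor(self.data.reshape(*shape), requires_grad=self.requires_grad, parents=(self,))

        def backward(g):
            self._accumulate(g.reshape(orig))

        out._backward = backward if self.requires_grad else None
        return out

    def slice_cols(self, start: int, stop: int) -> "Tensor":
        """Columns ``start:stop`` of a 2-D tensor (differentiable)."""
        out = Tensor(self.data[:, start:stop], requires_grad=self.requires_grad, parents=(self,))

        def backward(g):
            full = np.zeros_like(self.data)
            full[:, start:stop] = g
            self._accumulate(full)

        out._backward = backward if self.requires_grad else None
        return out


def concat(tensors, axis: int = 1) -> Tensor:
    """Differentiable concatenation along ``axis``."""
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    out = Tensor(data, requires_grad=req, parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]

    def backward(g):
        offset = 0
        for t, n in zip(tensors, sizes):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(offset, offset + n)
                t._accumulate(g[tuple(idx)])
            offset += n

    out._backward = backward if req else None
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Differentiable softmax along ``axis``."""
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, requires_grad=x.requires_grad, parents=(x,))

    def backward(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        x._accumulate(y * (g - dot))

    out._backward = backward if x.requires_grad else None
    return out


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer ``labels`` under row-wise softmax.

    Computed from logits with the log-sum-exp trick for stability; the
    public prediction contract elsewhere uses probabilities.
    """
    labels = np.asarray(labels, dtype=np.intp)
    n = logits.data.shape[0]
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1))
    loss = float(np.mean(lse - z[np.arange(n), labels]))
    out = Tensor(loss, requires_grad=logits.requires_grad, parents=(logits,))

    def backward(g):
        p = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
        p[np.arange(n), labels] -= 1.0
        logits._accumulate(g * p / n)

    out._backward = backward if logits.requires_grad else None
    return out


def take_columns(param: Tensor, idx: np.ndarray) -> Tensor:
    """Gather columns ``idx`` of a (K, N) tensor as a (len(idx), K) tensor.

    Gradient scatter-adds back into the gathered columns; used to pull the
    per-subject branch-selection logits for a mini-batch.
    """
    idx = np.asarray(idx, dtype=np.intp)
    out = Tensor(param.data[:, idx].T, requires_grad=param.requires_grad, parents=(param,))

    def backward(g):
        full = np.zeros_like(param.data)
        np.add.at(full.T, idx, g)
        param._accumulate(full)

    out._backward = backward if param.requires_grad else None
    return out


def take_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    """Differentiable row gather of a 2-D tensor."""
    idx = np.asarray(idx, dtype=np.intp)
    out = Tensor(x.data[idx], requires_grad=x.requires_grad, parents=(x,))

    def backward(g):
        full = np.zeros_like(x.data)
        np.add.at(full, idx, g)
        x._accumulate(full)

    out._backward = backward if x.requires_grad else None
    return out
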