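"""Neural-network building blocks on top of the autograd engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat

__all__ = ["Module", "Linear", "LSTM", "Adam"]


class Module:
    """Base class: recursively collects :class:`Tensor` parameters."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()

        def visit(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    visit(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    visit(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    visit(v)

        visit(self)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]


class Linear(Module):
    """Dense layer ``y = x W + b`` with Glorot-uniform initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = Tensor(rng.uniform(-limit, limit, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def copy_from(self, other: "Linear") -> None:
        self.W.data[...] = other.W.data
        self.b.data[...] = other.b.data


class LSTM(Module):
    """Single-layer LSTM; gate order (input, forget, cell, output).

    Forget-gate bias starts at 1, the usual remedy against vanishing
    memory early in training.
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_hidden = n_hidden
        limit = np.sqrt(6.0 / (n_in + n_hidden + 4 * n_hidden))
        self.W = Tensor(rng.uniform(-limit, limit, size=(n_in + n_hidden, 4 * n_hidden)),
                        requires_grad=True)
        b = np.zeros(4 * n_hidden)
        b[n_hidden:2 * n_hidden] = 1.0
        self.b = Tensor(b, requires_grad=True)

    def __call__(self, xs: list[Tensor]) -> tuple[list[Tensor], Tensor]:
        """Run over a list of (batch, n_in) steps; return (hidden states, last h)."""
        nh = self.n_hidden
        batch = xs[0].data.shape[0]
        h = Tensor(np.zeros((batch, nh)))
        c = Tensor(np.zeros((batch, nh)))
        hs: list[Tensor] = []
        for x in xs:
            z = concat([x, h], axis=1) @ self.W + self.b
            i = z.slice_cols(0, nh).sigmoid()
            f = z.slice_cols(nh, 2 * nh).sigmoid()
            g = z.slice_cols(2 * nh, 3 * nh).tanh()
            o = z.slice_cols(3 * nh, 4 * nh).sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            hs.append(h)
        return hs, h


class Adam:
    """Adam optimizer with optional per-parameter learning-rate override."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 lr_overrides: dict[int, float] | None = None):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.lr_overrides = lr_overrides or {}

    def step(self) -> None:
        self.t += 1
        for k, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            lr = self.lr_overrides.get(id(p), self.lr)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)
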