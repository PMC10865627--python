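"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations needed by the fusion channels, the stacked
autoencoders and the graph convolutional model: dense matrix products, bias
broadcasting, ReLU/sigmoid, row-softmax, elementwise arithmetic, row
gathering, column concatenation and scalar reductions.  Gradients are
accumulated by closure; ``backward`` walks the graph in reverse topological
order.  Everything is float64 and fully deterministic.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Var",
    "constant",
    "parameter",
    "matmul",
    "add",
    "sub",
    "mul",
    "scale",
    "relu",
    "sigmoid",
    "log",
    "softmax_rows",
    "take_rows",
    "concat_cols",
    "ssum",
    "smean",
    "sigmoid_bce_with_logits",
    "Adam",
    "RMSProp",
]


class Var:
    """A node in the computation graph holding a value and its gradient."""

    __slots__ = ("value", "grad", "parents", "_backward", "requires_grad")

    def __init__(
        self,
        value: np.ndarray,
        parents: Sequence["Var"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
        requires_grad: bool = True,
    ) -> None:
        self.value = np.asarray(value, dtype=np.float64)
        self.parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, ...]:
        return self.value.shape

    def accumulate(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.value)
        self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Backpropagate from this (scalar) node through the whole graph."""
        if self.value.ndim != 0:
            raise ValueError("backward() requires a scalar root node")
        order: list[Var] = []
        seen: set[int] = set()
        stack: list[tuple[Var, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.value)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def constant(value) -> Var:
    return Var(value, requires_grad=False)


def parameter(value) -> Var:
    return Var(np.array(value, dtype=np.float64, copy=True))


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def matmul(a: Var, b: Var) -> Var:
    out = Var(a.value @ b.value, (a, b))

    def bw(g: np.ndarray) -> None:
        a.accumulate(g @ b.value.T)
        b.accumulate(a.value.T @ g)

    out._backward = bw
    return out


def add(a: Var, b: Var) -> Var:
    out = Var(a.value + b.value, (a, b))

    def bw(g: np.ndarray) -> None:
        a.accumulate(_unbroadcast(g, a.value.shape))
        b.accumulate(_unbroadcast(g, b.value.shape))

    out._backward = bw
    return out


def sub(a: Var, b: Var) -> Var:
    out = Var(a.value - b.value, (a, b))

    def bw(g: np.ndarray) -> None:
        a.accumulate(_unbroadcast(g, a.value.shape))
        b.accumulate(-_unbroadcast(g, b.value.shape))

    out._backward = bw
    return out


def mul(a: Var, b: Var) -> Var:
    out = Var(a.value * b.value, (a, b))

    def bw(g: np.ndarray) -> None:
        a.accumulate(_unbroadcast(g * b.value, a.value.shape))
        b.accumulate(_unbroadcast(g * a.value, b.value.shape))

    out._backward = bw
    return out


def scale(x: Var, s: Var) -> Var:
    """Multiply array ``x`` by scalar node ``s``."""
    out = Var(s.value * x.value, (x, s))

    def bw(g: np.ndarray) -> None:
        x.accumulate(g * s.value)
        s.accumulate(np.sum(g * x.value))

    out._backward = bw
    return out


def relu(x: Var) -> Var:
    mask = x.value > 0
    out = Var(x.value * mask, (x,))

    def bw(g: np.ndarray) -> None:
        x.accumulate(g * mask)

    out._backward = bw
    return out


def sigmoid(x: Var) -> Var:
    s = 1.0 / (1.0 + np.exp(-x.value))
    out = Var(s, (x,))

    def bw(g: np.ndarray) -> None:
        x.accumulate(g * s * (1.0 - s))

    out._backward = bw
    return out


def log(x: Var) -> Var:
    out = Var(np.log(x.value), (x,))

    def bw(g: np.ndarray) -> None:
        x.accumulate(g / x.value)

    out._backward = bw
    return out


def softmax_rows(x: Var) -> Var:
    z = x.value - x.value.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)
    out = Var(p, (x,))

    def bw(g: np.ndarray) -> None:
        dot = np.sum(g * p, axis=-1, keepdims=True)
        x.accumulate((g - dot) * p)

    out._backward = bw
    return out


def take_rows(x: Var, idx: np.ndarray) -> Var:
    idx = np.asarray(idx, dtype=np.intp)
    out = Var(x.value[idx], (x,))

    def bw(g: np.ndarray) -> None:
        gx = np.zeros_like(x.value)
        np.add.at(gx, idx, g)
        x.accumulate(gx)

    out._backward = bw
    return out


def concat_cols(a: Var, b: Var) -> Var:
    na = a.value.shape[1]
    out = Var(np.concatenate([a.value, b.value], axis=1), (a, b))

    def bw(g: np.ndarray) -> None:
        a.accumulate(g[:, :na])
        b.accumulate(g[:, na:])

    out._backward = bw
    return out


def ssum(x: Var) -> Var:
    out = Var(np.asarray(x.value.sum()), (x,))

    def bw(g: np.ndarray) -> None:
        x.accumulate(np.full_like(x.value, float(g)))

    out._backward = bw
    return out


def smean(x: Var) -> Var:
    n = x.value.size
    out = Var(np.asarray(x.value.mean()), (x,))

    def bw(g: np.ndarray) -> None:
        x.accumulate(np.full_like(x.value, float(g) / n))

    out._backward = bw
    return out


def sigmoid_bce_with_logits(z: Var, labels: np.ndarray) -> Var:
    """Summed binary cross-entropy of sigmoid(z) against 0/1 labels.

    Numerically stable fused form: loss_i = max(z,0) - z*y + log(1+exp(-|z|)).
    """
    y = np.asarray(labels, dtype=np.float64).reshape(z.value.shape)
    zv = z.value
    loss = np.maximum(zv, 0.0) - zv * y + np.log1p(np.exp(-np.abs(zv)))
    out = Var(np.asarray(loss.sum()), (z,))
    s = 1.0 / (1.0 + np.exp(-zv))

    def bw(g: np.ndarray) -> None:
        z.accumulate(float(g) * (s - y))

    out._backward = bw
    return out


class _Optimizer:
    def __init__(self, params: Iterable[Var]) -> None:
        self.params = list(params)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class Adam(_Optimizer):
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        super().__init__(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad ** 2
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class RMSProp(_Optimizer):
    """Momentum-free adaptive-step gradient descent."""

    def __init__(self, params, lr=1e-3, decay=0.9, eps=1e-8):
        super().__init__(params)
        self.lr, self.decay, self.eps = lr, decay, eps
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.v[i] = self.decay * self.v[i] + (1 - self.decay) * p.grad ** 2
            p.value -= self.lr * p.grad / (np.sqrt(self.v[i]) + self.eps)
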