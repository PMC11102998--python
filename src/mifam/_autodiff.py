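"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Internal engine for the attention model: a ``Tensor`` wraps an ndarray and
records the operations applied to it; ``backward()`` walks the tape in
reverse topological order accumulating gradients.  Only the operations the
model needs are implemented (matmul, broadcast add, elementwise activations,
masked row softmax, concatenation, row gather, mean-squared error), each
with an explicit adjoint.  Adam is included as the single optimizer.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that broadcasting expanded to reach ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, value, requires_grad: bool = False):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], tuple[np.ndarray, ...]] | None = None

    @property
    def shape(self):
        return self.value.shape

    def backward(self) -> None:
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
                if id(p) not in seen:
                    stack.append((p, False))
        for node in topo:
            node.grad = np.zeros_like(node.value)
        self.grad = np.ones_like(self.value)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, pgrad in zip(node._parents, node._backward(node.grad)):
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.value)
                parent.grad += pgrad


def _make(value: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(value)
    out._parents = parents
    out._backward = backward
    out.requires_grad = any(p.requires_grad for p in parents)
    return out


def constant(value) -> Tensor:
    return Tensor(value, requires_grad=False)


def parameter(value) -> Tensor:
    return Tensor(np.array(value, dtype=np.float64), requires_grad=True)


def add(a: Tensor, b: Tensor) -> Tensor:
    return _make(
        a.value + b.value, (a, b),
        lambda g: (_unbroadcast(g, a.value.shape), _unbroadcast(g, b.value.shape)),
    )


def sub(a: Tensor, b: Tensor) -> Tensor:
    return _make(
        a.value - b.value, (a, b),
        lambda g: (_unbroadcast(g, a.value.shape), _unbroadcast(-g, b.value.shape)),
    )


def scale(a: Tensor, c: float) -> Tensor:
    return _make(a.value * c, (a,), lambda g: (g * c,))


def matmul(a: Tensor, b: Tensor) -> Tensor:
    return _make(
        a.value @ b.value, (a, b),
        lambda g: (g @ b.value.T, a.value.T @ g),
    )


def matvec(a: Tensor, v: Tensor) -> Tensor:
    """(n, d) @ (d,) -> (n,)."""
    return _make(
        a.value @ v.value, (a, v),
        lambda g: (np.outer(g, v.value), a.value.T @ g),
    )


def pairwise_sum(f: Tensor, g: Tensor) -> Tensor:
    """E[i, j] = f[i] + g[j] for vectors f, g of length n."""
    return _make(
        f.value[:, None] + g.value[None, :], (f, g),
        lambda gr: (gr.sum(axis=1), gr.sum(axis=0)),
    )


def transpose(a: Tensor) -> Tensor:
    return _make(a.value.T, (a,), lambda g: (g.T,))


def slice_vec(a: Tensor, start: int, stop: int) -> Tensor:
    """Slice of a 1-D tensor; the adjoint scatters back into place."""

    def backward(g: np.ndarray):
        out = np.zeros_like(a.value)
        out[start:stop] = g
        return (out,)

    return _make(a.value[start:stop], (a,), backward)


def relu(a: Tensor) -> Tensor:
    mask = a.value > 0
    return _make(np.where(mask, a.value, 0.0), (a,), lambda g: (g * mask,))


def leaky_relu(a: Tensor, slope: float) -> Tensor:
    mask = a.value > 0
    deriv = np.where(mask, 1.0, slope)
    return _make(np.where(mask, a.value, slope * a.value), (a,), lambda g: (g * deriv,))


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.value))
    return _make(s, (a,), lambda g: (g * s * (1.0 - s),))


def masked_softmax(a: Tensor, mask: np.ndarray) -> Tensor:
    """Row softmax restricted to ``mask`` (boolean); masked entries are 0.

    Computed with max-subtraction for overflow safety.  Rows with an empty
    mask would be ill-defined; the adjacency contract (self-loops) rules
    them out.
    """
    x = np.where(mask, a.value, -np.inf)
    x = x - x.max(axis=1, keepdims=True)
    e = np.exp(x)
    p = e / e.sum(axis=1, keepdims=True)

    def backward(g: np.ndarray):
        dot = (g * p).sum(axis=1, keepdims=True)
        return ((g - dot) * p,)

    return _make(p, (a,), backward)


def concat_cols(tensors: list[Tensor]) -> Tensor:
    widths = [t.value.shape[1] for t in tensors]
    splits = np.cumsum(widths)[:-1]
    return _make(
        np.concatenate([t.value for t in tensors], axis=1),
        tuple(tensors),
        lambda g: tuple(np.split(g, splits, axis=1)),
    )


def gather_rows(a: Tensor, idx: np.ndarray) -> Tensor:
    idx = np.asarray(idx, dtype=np.intp)

    def backward(g: np.ndarray):
        out = np.zeros_like(a.value)
        np.add.at(out, idx, g)
        return (out,)

    return _make(a.value[idx], (a,), backward)


def mean_tensors(tensors: list[Tensor]) -> Tensor:
    k = len(tensors)
    return _make(
        sum(t.value for t in tensors) / k,
        tuple(tensors),
        lambda g: tuple(g / k for _ in tensors),
    )


def mse(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred.value - np.asarray(target, dtype=np.float64)
    n = diff.size
    return _make(
        np.array((diff ** 2).mean()), (pred,),
        lambda g: (g * 2.0 * diff / n,),
    )


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.value)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
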