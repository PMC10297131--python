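"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just the operations the model zoo needs: dense and sparse matrix products,
bias broadcasting, elementwise activations, row gathering, and the scalar
reductions used by the training loss. Every gradient is exercised against
central finite differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp


class Tensor:
    """A node in the computation graph.

    ``value`` is a numpy array (updated in place by optimizers for
    parameter leaves); ``grad`` is populated by :func:`backward`.
    """

    __slots__ = ("value", "parents", "grad_fn", "grad")

    def __init__(self, value, parents: Sequence["Tensor"] = (),
                 grad_fn: Optional[Callable] = None):
        self.value = np.asarray(value, dtype=float)
        self.parents = tuple(parents)
        self.grad_fn = grad_fn
        self.grad: Optional[np.ndarray] = None

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.value.shape

    def zero_grad(self) -> None:
        self.grad = None


def _topo(t: Tensor) -> List[Tensor]:
    order, seen = [], set()

    def visit(node: Tensor) -> None:
        if id(node) in seen:
            return
        seen.add(id(node))
        for p in node.parents:
            visit(p)
        order.append(node)

    visit(t)
    return order


def backward(t: Tensor) -> None:
    """Accumulate gradients of scalar ``t`` into every reachable tensor."""
    if t.value.ndim != 0:
        raise ValueError("backward requires a scalar output")
    for node in _topo(t):
        node.grad = None
    t.grad = np.ones_like(t.value)
    for node in reversed(_topo(t)):
        if node.grad_fn is None or node.grad is None:
            continue
        grads = node.grad_fn(node.grad)
        for parent, g in zip(node.parents, grads):
            if g is None:
                continue
            parent.grad = g if parent.grad is None else parent.grad + g


# -- operations -------------------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = a.value @ b.value

    def grad_fn(g):
        return g @ b.value.T, a.value.T @ g

    return Tensor(out, (a, b), grad_fn)


def spmm(S: sp.spmatrix, a: Tensor) -> Tensor:
    """Sparse constant matrix times dense tensor."""
    out = S @ a.value

    def grad_fn(g):
        return (S.T @ g,)

    return Tensor(out, (a,), grad_fn)


def add_bias(a: Tensor, b: Tensor) -> Tensor:
    """(n, m) + (m,) broadcast."""
    out = a.value + b.value

    def grad_fn(g):
        return g, g.sum(axis=0)

    return Tensor(out, (a, b), grad_fn)


def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.value + b.value

    def grad_fn(g):
        return g, g

    return Tensor(out, (a, b), grad_fn)


def scale(a: Tensor, c: float) -> Tensor:
    out = a.value * c

    def grad_fn(g):
        return (g * c,)

    return Tensor(out, (a,), grad_fn)


def relu(a: Tensor) -> Tensor:
    out = np.maximum(a.value, 0.0)

    def grad_fn(g):
        return (g * (a.value > 0),)

    return Tensor(out, (a,), grad_fn)


def leaky_relu(a: Tensor, alpha: float = 0.01) -> Tensor:
    out = np.where(a.value > 0, a.value, alpha * a.value)

    def grad_fn(g):
        return (g * np.where(a.value > 0, 1.0, alpha),)

    return Tensor(out, (a,), grad_fn)


def sigmoid(a: Tensor) -> Tensor:
    out = 1.0 / (1.0 + np.exp(-a.value))

    def grad_fn(g):
        return (g * out * (1.0 - out),)

    return Tensor(out, (a,), grad_fn)


def identity(a: Tensor) -> Tensor:
    return a


ACTIVATIONS = {"relu": relu, "leaky_relu": leaky_relu, "sigmoid": sigmoid,
               "identity": identity}


def ravel(a: Tensor) -> Tensor:
    shape = a.value.shape
    out = a.value.ravel()

    def grad_fn(g):
        return (g.reshape(shape),)

    return Tensor(out, (a,), grad_fn)


def gather_rows(a: Tensor, idx: np.ndarray) -> Tensor:
    idx = np.asarray(idx, dtype=int)
    out = a.value[idx]

    def grad_fn(g):
        full = np.zeros_like(a.value)
        np.add.at(full, idx, g)
        return (full,)

    return Tensor(out, (a,), grad_fn)


def sumsq(a: Tensor) -> Tensor:
    out = np.asarray((a.value ** 2).sum())

    def grad_fn(g):
        return (2.0 * g * a.value,)

    return Tensor(out, (a,), grad_fn)


def bce_mean(scores: Tensor, labels: np.ndarray,
             eps: float = 1e-12) -> Tensor:
    """Mean binary cross-entropy with probability clamping at ``eps``."""
    y = np.asarray(labels, dtype=float)
    if scores.value.shape != y.shape:
        raise ValueError(
            f"scores shape {scores.value.shape} != labels shape {y.shape}")
    if y.size == 0:
        raise ValueError("empty supervision set")
    p = np.clip(scores.value, eps, 1.0 - eps)
    out = np.asarray(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).mean())
    inside = (scores.value > eps) & (scores.value < 1.0 - eps)

    def grad_fn(g):
        d = np.where(inside, (-(y / p) + (1.0 - y) / (1.0 - p)) / y.size, 0.0)
        return (g * d,)

    return Tensor(out, (scores,), grad_fn)
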