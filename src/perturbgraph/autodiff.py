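"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the two GNN modules need: broadcasting
arithmetic, (batched) matrix products, elementwise nonlinearities, stable
binary cross-entropy pieces, reductions, concatenation, and per-node
embedding-table gathers. Gradients are accumulated into leaf tensors with
``requires_grad=True``; correctness is checked against central finite
differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional, Sequence

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Optional[Callable[[np.ndarray], None]] = None,
    ):
        self.data = np.asarray(data)
        if self.data.dtype not in (np.float32, np.float64):
            self.data = self.data.astype(np.float64)
        self.grad: Optional[np.ndarray] = None
        self._parents = tuple(parents)
        self._backward = backward
        # a node needs grad if it is a leaf parameter or any ancestor is
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    # -- infrastructure ------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Backpropagate; ``grad`` defaults to ones (use on scalars)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self.grad = np.ones_like(self.data) if grad is None \
            else np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def accumulate(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        g = _unbroadcast(np.asarray(grad), self.data.shape)
        # grads are never mutated in place (accumulation allocates), so
        # storing by reference — even views of upstream grads — is safe
        self.grad = g if self.grad is None else self.grad + g

    def zero_grad(self) -> None:
        self.grad = None

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic ----------------------------------------------------

    def __add__(self, other):
        if isinstance(other, (int, float)):
            out = Tensor(self.data + other, parents=(self,))
            out._backward = lambda g: self.accumulate(g)
            return out
        other = as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))
        out._backward = lambda g: (self.accumulate(g), other.accumulate(g))
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self.accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            out = Tensor(self.data * other, parents=(self,))
            out._backward = lambda g: self.accumulate(g * other)
            return out
        other = as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))
        out._backward = lambda g: (
            self.accumulate(g * other.data),
            other.accumulate(g * self.data),
        )
        return out

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g):
            a, b = self.data, other.data
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            self.accumulate(_unbroadcast(ga, a.shape))
            other.accumulate(_unbroadcast(gb, b.shape))

        out._backward = bw
        return out

    # -- reductions & shape --------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self.accumulate(np.broadcast_to(g, self.data.shape))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        size = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / size)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(shape), parents=(self,))
        out._backward = lambda g: self.accumulate(g.reshape(self.data.shape))
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data) -> Tensor:
    return Tensor(np.asarray(data, float), requires_grad=True)


# ---------------------------------------------------------------------------
# Nonlinearities and composite ops
# ---------------------------------------------------------------------------


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), parents=(x,))
    out._backward = lambda g: x.accumulate(g * (x.data > 0))
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))
    out = Tensor(s, parents=(x,))
    out._backward = lambda g: x.accumulate(g * s * (1.0 - s))
    return out


def log(x: Tensor) -> Tensor:
    out = Tensor(np.log(x.data), parents=(x,))
    out._backward = lambda g: x.accumulate(g / x.data)
    return out


def softplus(x: Tensor) -> Tensor:
    """log(1 + exp(x)), computed stably."""
    z = x.data
    val = np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z)))
    out = Tensor(val, parents=(x,))
    s = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
    out._backward = lambda g: x.accumulate(g * s)
    return out


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t.accumulate(piece)

    out._backward = bw
    return out


def gather_nodes(table: Tensor, idx: np.ndarray) -> Tensor:
    """Per-node embedding lookup.

    ``table`` has shape (n, B, d); ``idx`` is an integer array (S, n) of
    bin indices; output (S, n, d) with out[s, i] = table[i, idx[s, i]].
    """
    idx = np.asarray(idx)
    S, n = idx.shape
    ar = np.arange(n)
    out = Tensor(table.data[ar[None, :], idx], parents=(table,))

    def bw(g):
        if not table.requires_grad:
            return
        grad = np.zeros_like(table.data)
        np.add.at(grad, (np.broadcast_to(ar[None, :], idx.shape), idx), g)
        table.accumulate(grad)

    out._backward = bw
    return out


def _single_mm(A: np.ndarray, X: np.ndarray) -> np.ndarray:
    """(n, n) @ (S, n, F) as one GEMM via a transpose trick."""
    S, n, F = X.shape
    Xt = np.ascontiguousarray(X.transpose(1, 0, 2)).reshape(n, S * F)
    return (A @ Xt).reshape(n, S, F).transpose(1, 0, 2)


def matmul_const(A: np.ndarray, H: Tensor) -> Tensor:
    """Product of a constant matrix (stack) with a tensor: A @ H.

    ``A`` may be (n, n) or batched (S, n, n); gradient flows to H only.
    Used for neighborhood aggregation with fixed (mutilated) adjacency.
    The unbatched case runs as a single GEMM.
    """
    A = np.asarray(A, dtype=H.data.dtype)
    if A.ndim == 2 and H.data.ndim == 3:
        out = Tensor(_single_mm(A, H.data), parents=(H,))
        out._backward = lambda g: H.accumulate(_single_mm(A.T, g))
        return out
    out = Tensor(A @ H.data, parents=(H,))
    out._backward = lambda g: H.accumulate(np.swapaxes(A, -1, -2) @ g)
    return out


def grouped_matmul(A_stack: np.ndarray, slices: Sequence[slice], H: Tensor) -> Tensor:
    """Per-group aggregation: samples in ``slices[g]`` are multiplied by
    ``A_stack[g]``.

    Equivalent to a per-sample batched matmul when samples sharing an
    adjacency are contiguous, but runs one GEMM per group.
    """
    A_stack = np.asarray(A_stack, dtype=H.data.dtype)

    def apply(mats: np.ndarray, X: np.ndarray) -> np.ndarray:
        out = np.empty_like(X)
        for g, sl in enumerate(slices):
            out[sl] = _single_mm(mats[g], X[sl])
        return out

    out = Tensor(apply(A_stack, H.data), parents=(H,))
    At = np.ascontiguousarray(np.swapaxes(A_stack, -1, -2))
    out._backward = lambda g: H.accumulate(apply(At, g))
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray,
                    weights: Optional[np.ndarray] = None) -> Tensor:
    """Mean binary cross-entropy with continuous targets, from logits.

    CE(t, sigmoid(z)) = softplus(z) - t * z, numerically stable for any z.
    ``weights`` are fixed per-element multipliers (e.g. positive-class
    weighting); the mean is over all elements, weighted.
    """
    t = np.asarray(targets, dtype=logits.data.dtype)
    ce = softplus(logits) + logits * (-t)
    if weights is not None:
        ce = ce * np.asarray(weights, dtype=logits.data.dtype)
    return ce.mean()


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------


class Adam:
    """Adam optimizer over a flat list of parameter tensors."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
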