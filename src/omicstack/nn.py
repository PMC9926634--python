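"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Provides exactly the primitives the integration architectures need: dense
layers, ReLU/sigmoid/softmax, dropout, batched matmul (for module attention),
stable binary cross-entropy from logits, and an Adagrad optimizer with L2
weight decay.  Everything is float64 and driven by explicit
``numpy.random.Generator`` instances, so training trajectories are
bit-reproducible for a fixed seed.

The tape is define-by-run: each operation returns a new :class:`Var` holding
its inputs and a closure that maps the output gradient to input gradients;
:meth:`Var.backward` walks the tape in reverse topological order.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Var",
    "Param",
    "Linear",
    "Dropout",
    "Adagrad",
    "relu",
    "sigmoid",
    "softplus",
    "softmax",
    "concat",
    "take_rows",
    "bce_with_logits",
    "bce_probs",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Var:
    """A node in the autodiff tape."""

    __slots__ = ("data", "grad", "_parents", "_vjp", "requires_grad")

    def __init__(self, data, parents: tuple["Var", ...] = (),
                 vjp: Callable[[np.ndarray], tuple[np.ndarray, ...]] | None = None,
                 requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._vjp = vjp
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    # -- graph walk ---------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Var] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: tapes can be deep
            node, expanded = stack.pop()
            if id(node) in seen:
                continue
            if expanded:
                seen.add(id(node))
                topo.append(node)
            else:
                stack.append((node, True))
                for p in node._parents:
                    if id(p) not in seen and p.requires_grad:
                        stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._vjp is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._vjp(node.grad)):
                if not parent.requires_grad or g is None:
                    continue
                parent.grad = g if parent.grad is None else parent.grad + g

    def detach(self) -> "Var":
        return Var(self.data)

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Var) else Var(other)
        return Var(self.data + other.data, (self, other),
                   lambda g: (_unbroadcast(g, self.data.shape),
                              _unbroadcast(g, other.data.shape)))

    __radd__ = __add__

    def __neg__(self):
        return Var(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        other = other if isinstance(other, Var) else Var(other)
        return self + (-other)

    def __rsub__(self, other):
        return Var(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Var) else Var(other)
        return Var(self.data * other.data, (self, other),
                   lambda g: (_unbroadcast(g * other.data, self.data.shape),
                              _unbroadcast(g * self.data, other.data.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Var) else Var(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Var(other) * self ** -1.0

    def __pow__(self, exponent: float):
        d = self.data
        out = d ** exponent
        return Var(out, (self,), lambda g: (g * exponent * d ** (exponent - 1.0),))

    def __matmul__(self, other):
        other = other if isinstance(other, Var) else Var(other)
        a, b = self.data, other.data

        def vjp(g):
            ga = _unbroadcast(np.matmul(g, np.swapaxes(b, -1, -2)), a.shape)
            gb = _unbroadcast(np.matmul(np.swapaxes(a, -1, -2), g), b.shape)
            return ga, gb

        return Var(np.matmul(a, b), (self, other), vjp)

    # -- reductions / reshaping --------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def vjp(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.data.shape).copy(),)

        return Var(out, (self,), vjp)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        orig = self.data.shape
        return Var(self.data.reshape(*shape), (self,),
                   lambda g: (g.reshape(orig),))

    def transpose(self, *axes):
        inv = np.argsort(axes)
        return Var(self.data.transpose(*axes), (self,),
                   lambda g: (g.transpose(*inv),))


class Param(Var):
    """A trainable leaf; optimizers update ``data`` in place."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# -- elementwise nonlinearities ---------------------------------------------

def relu(x: Var) -> Var:
    mask = x.data > 0
    return Var(x.data * mask, (x,), lambda g: (g * mask,))


def exp(x: Var) -> Var:
    out = np.exp(x.data)
    return Var(out, (x,), lambda g: (g * out,))


def log(x: Var) -> Var:
    return Var(np.log(x.data), (x,), lambda g: (g / x.data,))


def sigmoid(x: Var) -> Var:
    out = 0.5 * (1.0 + np.tanh(0.5 * x.data))  # numerically stable
    return Var(out, (x,), lambda g: (g * out * (1.0 - out),))


def softplus(x: Var) -> Var:
    d = x.data
    out = np.maximum(d, 0.0) + np.log1p(np.exp(-np.abs(d)))
    s = 0.5 * (1.0 + np.tanh(0.5 * d))

    return Var(out, (x,), lambda g: (g * s,))


def softmax(x: Var, axis: int = -1) -> Var:
    m = x.data.max(axis=axis, keepdims=True)
    e = exp(x - m)
    return e / e.sum(axis=axis, keepdims=True)


def concat(xs: Sequence[Var], axis: int = 1) -> Var:
    xs = list(xs)
    sizes = [x.data.shape[axis] for x in xs]
    splits = np.cumsum(sizes)[:-1]

    def vjp(g):
        return tuple(np.split(g, splits, axis=axis))

    return Var(np.concatenate([x.data for x in xs], axis=axis), tuple(xs), vjp)


def take_rows(x: Var, idx: np.ndarray) -> Var:
    """Row gather with scatter-add backward (for triplet index sets)."""
    idx = np.asarray(idx, dtype=int)

    def vjp(g):
        out = np.zeros_like(x.data)
        np.add.at(out, idx, g)
        return (out,)

    return Var(x.data[idx], (x,), vjp)


# -- losses ------------------------------------------------------------------

def bce_with_logits(logits: Var, targets: np.ndarray, reduction: str = "mean") -> Var:
    """Binary cross-entropy from raw scores: softplus(z) - y*z, numerically safe."""
    t = Var(np.asarray(targets, dtype=float))
    per = softplus(logits) - logits * t
    if reduction == "mean":
        return per.mean()
    if reduction == "sum":
        return per.sum()
    return per


def bce_probs(probs: Var, targets: np.ndarray, eps: float = 1e-7,
              reduction: str = "mean") -> Var:
    """BCE on probabilities already in (0,1); clipped at ``eps`` to avoid log(0)."""
    p = Var(np.clip(probs.data, eps, 1.0 - eps), (probs,),
            lambda g: (g * ((probs.data > eps) & (probs.data < 1.0 - eps)),))
    t = np.asarray(targets, dtype=float)
    per = -(Var(t) * log(p) + Var(1.0 - t) * log(1.0 - p))
    if reduction == "mean":
        return per.mean()
    if reduction == "sum":
        return per.sum()
    return per


# -- layers ------------------------------------------------------------------

class Linear:
    """Dense layer, Glorot-uniform initialized from the supplied generator."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = math.sqrt(6.0 / (n_in + n_out))
        self.W = Param(rng.uniform(-limit, limit, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))

    def __call__(self, x: Var) -> Var:
        return x @ self.W + self.b

    def params(self) -> list[Param]:
        return [self.W, self.b]


class Dropout:
    """Inverted dropout; identity when ``training`` is False."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.p = p
        self.rng = rng
        self.training = True

    def __call__(self, x: Var) -> Var:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.data.shape) >= self.p) / (1.0 - self.p)
        return x * Var(mask)


class Adagrad:
    """Adagrad with decoupled-into-gradient L2 penalty (weight decay)."""

    def __init__(self, params: Iterable[Param], lr: float,
                 weight_decay: float = 0.0, eps: float = 1e-10):
        self.params = list(params)
        self.lr = lr
        self.weight_decay = weight_decay
        self.eps = eps
        self._accum = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, acc in zip(self.params, self._accum):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            acc += g * g
            p.data -= self.lr * g / (np.sqrt(acc) + self.eps)
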