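"""Minimal reverse-mode automatic differentiation over numpy arrays.

Small, dependency-free engine supporting exactly the operations the
encoder needs: broadcasting arithmetic, (batched) matmul, relu/sigmoid,
row softmax, reductions, reshapes and concatenation, plus an Adam
optimizer.  Everything is float64 and deterministic: identical inputs
and op order give bitwise-identical results.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "dropout", "Adam", "glorot_uniform"]


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
    return grad


class Tensor:
    """A numpy array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _ensure(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = Tensor._ensure(other)
        return Tensor._make(
            self.data + other.data,
            (self, other),
            lambda g: [
                (self, _unbroadcast(g, self.data.shape)),
                (other, _unbroadcast(g, other.data.shape)),
            ],
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: [(self, -g)])

    def __sub__(self, other):
        return self + (-Tensor._ensure(other))

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        other = Tensor._ensure(other)
        return Tensor._make(
            self.data * other.data,
            (self, other),
            lambda g: [
                (self, _unbroadcast(g * other.data, self.data.shape)),
                (other, _unbroadcast(g * self.data, other.data.shape)),
            ],
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return self * (other ** -1.0)
        return self * (1.0 / other)

    def __pow__(self, p: float):
        data = self.data ** p
        return Tensor._make(
            data, (self,), lambda g: [(self, g * p * self.data ** (p - 1.0))]
        )

    def __matmul__(self, other):
        other = Tensor._ensure(other)

        def backward(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return [
                (self, _unbroadcast(ga, self.data.shape)),
                (other, _unbroadcast(gb, other.data.shape)),
            ]

        return Tensor._make(self.data @ other.data, (self, other), backward)

    # -- elementwise nonlinearities ------------------------------------------
    def exp(self):
        data = np.exp(self.data)
        return Tensor._make(data, (self,), lambda g: [(self, g * data)])

    def log(self):
        return Tensor._make(
            np.log(self.data), (self,), lambda g: [(self, g / self.data)]
        )

    def relu(self):
        mask = self.data > 0
        return Tensor._make(
            np.where(mask, self.data, 0.0), (self,), lambda g: [(self, g * mask)]
        )

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(s, (self,), lambda g: [(self, g * s * (1.0 - s))])

    def softmax(self):
        """Softmax along the last axis."""
        z = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=-1, keepdims=True)

        def backward(g):
            return [(self, s * (g - (g * s).sum(axis=-1, keepdims=True)))]

        return Tensor._make(s, (self,), backward)

    # -- reductions / shape ops ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                return [(self, np.broadcast_to(g, self.data.shape).copy())]
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            return [(self, np.broadcast_to(gg, self.data.shape).copy())]

        return Tensor._make(data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        old = self.data.shape
        return Tensor._make(
            self.data.reshape(*shape), (self,), lambda g: [(self, g.reshape(old))]
        )

    def transpose(self, *axes):
        inv = tuple(int(i) for i in np.argsort(axes))
        return Tensor._make(
            self.data.transpose(axes), (self,), lambda g: [(self, g.transpose(inv))]
        )

    def swap_last(self):
        """Transpose the last two axes (any number of leading batch dims)."""
        data = np.swapaxes(self.data, -1, -2)
        return Tensor._make(
            data, (self,), lambda g: [(self, np.swapaxes(g, -1, -2))]
        )

    # -- backprop ------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is None:
                t.grad = g if t.grad is None else t.grad + g
                continue
            for p, pg in t._backward(g):
                if not p.requires_grad:
                    continue
                k = id(p)
                grads[k] = pg if k not in grads else grads[k] + pg


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._ensure(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        return list(zip(tensors, parts))

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                   shape: tuple[int, ...] | None = None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


class Adam:
    """Adam with the standard moment defaults."""

    def __init__(self, params: Iterable[Tensor], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            mhat = m / (1.0 - b1 ** self.t)
            vhat = v / (1.0 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
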