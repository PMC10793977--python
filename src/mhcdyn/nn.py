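"""Minimal reverse-mode automatic differentiation for the classifier networks.

A compact numpy-backed tensor graph supporting exactly the operations the
immunogenicity networks need: broadcast add/multiply, (batched) matmul, ReLU,
axis reductions (sum/mean/max), concatenation, slicing, gather along axis 1,
and a fused softmax cross-entropy. Gradients are checked against finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """Node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=float)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is None:  # leaf
                t.grad = g if t.grad is None else t.grad + g
                continue
            for p, pg in zip(t._prev, t._backward(g)):
                if not p.requires_grad or pg is None:
                    continue
                key = id(p)
                grads[key] = pg if key not in grads else grads[key] + pg

    # -- helpers -----------------------------------------------------------

    @staticmethod
    def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
        while g.ndim > len(shape):
            g = g.sum(axis=0)
        for ax, s in enumerate(shape):
            if s == 1 and g.shape[ax] != 1:
                g = g.sum(axis=ax, keepdims=True)
        return g.reshape(shape)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        o = self._wrap(other)
        return self._make(
            self.data + o.data,
            (self, o),
            lambda g: (self._unbroadcast(g, self.shape), self._unbroadcast(g, o.shape)),
        )

    __radd__ = __add__

    def __mul__(self, other):
        o = self._wrap(other)
        return self._make(
            self.data * o.data,
            (self, o),
            lambda g: (
                self._unbroadcast(g * o.data, self.shape),
                self._unbroadcast(g * self.data, o.shape),
            ),
        )

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __matmul__(self, other):
        o = self._wrap(other)

        def backward(g):
            ga = np.matmul(g, np.swapaxes(o.data, -1, -2))
            gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
            return self._unbroadcast(ga, self.shape), self._unbroadcast(gb, o.shape)

        return self._make(np.matmul(self.data, o.data), (self, o), backward)

    # -- nonlinearity and reductions ----------------------------------------

    def relu(self):
        mask = self.data > 0
        return self._make(self.data * mask, (self,), lambda g: (g * mask,))

    def sum(self, axis=None):
        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            return (np.broadcast_to(np.expand_dims(g, axis), self.shape).copy(),)

        return self._make(self.data.sum(axis=axis), (self,), backward)

    def mean(self, axis=None):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)

    def max(self, axis: int):
        idx = self.data.argmax(axis=axis)
        out = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis).squeeze(axis)

        def backward(g):
            grad = np.zeros_like(self.data)
            np.put_along_axis(
                grad, np.expand_dims(idx, axis), np.expand_dims(g, axis), axis=axis
            )
            return (grad,)

        return self._make(out, (self,), backward)

    # -- shape ops -----------------------------------------------------------

    def reshape(self, *shape):
        old = self.shape
        return self._make(
            self.data.reshape(*shape), (self,), lambda g: (g.reshape(old),)
        )

    def __getitem__(self, key):
        def backward(g):
            grad = np.zeros_like(self.data)
            np.add.at(grad, key, g)
            return (grad,)

        return self._make(self.data[key], (self,), backward)

    def take_axis1(self, idx: np.ndarray):
        """Gather along axis 1: data (B, D), idx any integer shape -> (B, *idx.shape)."""
        idx = np.asarray(idx, dtype=int)

        def backward(g):
            grad = np.zeros_like(self.data)
            b = np.arange(self.data.shape[0]).reshape((-1,) + (1,) * idx.ndim)
            np.add.at(grad, (b, idx[None, ...]), g)
            return (grad,)

        return self._make(self.data[:, idx], (self,), backward)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    out = Tensor(np.concatenate(datas, axis=axis),
                 requires_grad=any(t.requires_grad for t in tensors))
    if out.requires_grad:
        out._prev = tuple(tensors)
        out._backward = backward
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    """Plain numpy softmax over the last axis (inference only)."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of a softmax over the last axis; fused for stability.

    ``labels`` are integer class indices of shape (batch,).
    """
    labels = np.asarray(labels, dtype=int)
    probs = softmax(logits.data)
    n = len(labels)
    nll = -np.log(np.clip(probs[np.arange(n), labels], 1e-300, None))

    def backward(g):
        grad = probs.copy()
        grad[np.arange(n), labels] -= 1.0
        return (g * grad / n,)

    out = Tensor(nll.mean(), requires_grad=logits.requires_grad)
    if out.requires_grad:
        out._prev = (logits,)
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# Parameters and optimizers
# ---------------------------------------------------------------------------


def he_init(rng: np.random.Generator, n_in: int, n_out: int) -> Tensor:
    return Tensor(rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)),
                  requires_grad=True)


def zeros(shape) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


class SGD:
    """Plain stochastic gradient descent."""

    def __init__(self, params: list[Tensor], lr: float = 0.05):
        self.params = params
        self.lr = lr

    def step(self):
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * p.grad

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class Adam:
    """Adaptive-moment estimation optimizer."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
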