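"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the synergy predictor and the expression
autoencoder need: affine maps, batched matrix products, ReLU/sigmoid
nonlinearities, a numerically stable softmax, stacking/flattening of
attention tokens, a strided 1-D unfold for the convolutional drug-target
encoder, and scalar reductions for losses.  Gradients propagate through a
topologically sorted tape; broadcasting is undone by summing over the
broadcast axes.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "stack", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape`."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple = ()

    @property
    def shape(self):
        return self.data.shape

    # ------------------------------------------------------------------ ops
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad)
        out._parents = (self, other)

        def _bw(g):
            return (_unbroadcast(g, self.data.shape),
                    _unbroadcast(g, other.data.shape))
        out._backward = _bw
        return out

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad)
        out._parents = (self, other)

        def _bw(g):
            return (_unbroadcast(g * other.data, self.data.shape),
                    _unbroadcast(g * self.data, other.data.shape))
        out._backward = _bw
        return out

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    __radd__ = __add__
    __rmul__ = __mul__

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(np.matmul(self.data, other.data),
                     self.requires_grad or other.requires_grad)
        out._parents = (self, other)

        def _bw(g):
            a, b = self.data, other.data
            ga = np.matmul(g, np.swapaxes(b, -1, -2))
            gb = np.matmul(np.swapaxes(a, -1, -2), g)
            return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))
        out._backward = _bw
        return out

    __matmul__ = matmul

    def transpose_last(self) -> "Tensor":
        out = Tensor(np.swapaxes(self.data, -1, -2), self.requires_grad)
        out._parents = (self,)
        out._backward = lambda g: (np.swapaxes(g, -1, -2),)
        return out

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(self.data * mask, self.requires_grad)
        out._parents = (self,)
        out._backward = lambda g: (g * mask,)
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        out = Tensor(s, self.requires_grad)
        out._parents = (self,)
        out._backward = lambda g: (g * s * (1.0 - s),)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), self.requires_grad)
        out._parents = (self,)
        out._backward = lambda g: (g / self.data,)
        return out

    def clip(self, lo: float, hi: float) -> "Tensor":
        mask = (self.data > lo) & (self.data < hi)
        out = Tensor(np.clip(self.data, lo, hi), self.requires_grad)
        out._parents = (self,)
        out._backward = lambda g: (g * mask,)
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, self.requires_grad)
        out._parents = (self,)

        def _bw(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            return ((g - dot) * s,)
        out._backward = _bw
        return out

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad)
        out._parents = (self,)

        def _bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.data.shape).copy(),)
        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), self.requires_grad)
        out._parents = (self,)
        out._backward = lambda g: (g.reshape(self.data.shape),)
        return out

    def unfold(self, size: int, stride: int) -> "Tensor":
        """Sliding windows over the last axis: (..., T) -> (..., L, size)."""
        T = self.data.shape[-1]
        L = (T - size) // stride + 1
        idx = (np.arange(L)[:, None] * stride) + np.arange(size)[None, :]
        out = Tensor(self.data[..., idx], self.requires_grad)
        out._parents = (self,)

        def _bw(g):
            gx = np.zeros_like(self.data)
            np.add.at(gx, (..., idx), g)
            return (gx,)
        out._backward = _bw
        return out

    # ------------------------------------------------------------- backward
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)
        visit(self)
        grads = {id(self): np.ones_like(self.data)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None or t._backward is None:
                if g is not None and t.requires_grad:
                    t.grad = g if t.grad is None else t.grad + g
                continue
            if t.requires_grad:
                t.grad = g if t.grad is None else t.grad + g
            for parent, pg in zip(t._parents, t._backward(g)):
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg


def stack(tensors, axis: int = 1) -> Tensor:
    """Stack tensors of equal shape along a new axis (autodiff-aware)."""
    data = np.stack([t.data for t in tensors], axis=axis)
    out = Tensor(data, any(t.requires_grad for t in tensors))
    out._parents = tuple(tensors)

    def _bw(g):
        return tuple(np.take(g, i, axis=axis) for i in range(len(tensors)))
    out._backward = _bw
    return out


def concat(tensors, axis: int = -1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data, any(t.requires_grad for t in tensors))
    out._parents = tuple(tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def _bw(g):
        return tuple(np.split(g, splits, axis=axis))
    out._backward = _bw
    return out


class Adam:
    """Adaptive-moment gradient descent over a list of parameter Tensors."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
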