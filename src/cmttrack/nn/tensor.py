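"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small engine: just the operations the segmentation unit,
the test-time-adaptation losses and the tracking heads need.  Arrays are
float64 throughout; graphs are built eagerly and freed after ``backward``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "stack", "minimum", "maximum"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None,
                 name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = backward
        self._parents = parents
        self.name = name

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)
        # release graph references so intermediates can be collected
        for t in topo:
            if t is not self:
                t._backward = None
                t._parents = ()

    def _accum(self, g):
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad = self.grad + g

    @staticmethod
    def _make(data, parents, backward):
        req = any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=req, parents=tuple(parents) if req else (),
                      backward=backward if req else None)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor._make(self.data + other.data, (self, other), None)

        def bwd(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)
        out._backward = bwd
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor._make(self.data * other.data, (self, other), None)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)
        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor._make(self.data / other.data, (self, other), None)

        def bwd(g):
            if self.requires_grad:
                self._accum(g / other.data)
            if other.requires_grad:
                other._accum(-g * self.data / (other.data ** 2))
        out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        out = Tensor._make(self.data ** exponent, (self,), None)

        def bwd(g):
            self._accum(g * exponent * self.data ** (exponent - 1))
        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor._make(self.data @ other.data, (self, other), None)

        def bwd(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)
        out._backward = bwd
        return out

    # --------------------------------------------------------------- pointwise
    def exp(self):
        val = np.exp(self.data)
        out = Tensor._make(val, (self,), None)

        def bwd(g):
            self._accum(g * val)
        out._backward = bwd
        return out

    def log(self):
        out = Tensor._make(np.log(self.data), (self,), None)

        def bwd(g):
            self._accum(g / self.data)
        out._backward = bwd
        return out

    def sigmoid(self):
        val = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor._make(val, (self,), None)

        def bwd(g):
            self._accum(g * val * (1.0 - val))
        out._backward = bwd
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor._make(self.data * mask, (self,), None)

        def bwd(g):
            self._accum(g * mask)
        out._backward = bwd
        return out

    def sqrt(self):
        val = np.sqrt(self.data)
        out = Tensor._make(val, (self,), None)

        def bwd(g):
            self._accum(g * 0.5 / val)
        out._backward = bwd
        return out

    def arctan(self):
        out = Tensor._make(np.arctan(self.data), (self,), None)

        def bwd(g):
            self._accum(g / (1.0 + self.data ** 2))
        out._backward = bwd
        return out

    def clamp(self, lo: float, hi: float):
        """Clip values; gradient passes only where unclipped."""
        mask = (self.data >= lo) & (self.data <= hi)
        out = Tensor._make(np.clip(self.data, lo, hi), (self,), None)

        def bwd(g):
            self._accum(g * mask)
        out._backward = bwd
        return out

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        out = Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)

        def bwd(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))
        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        """Max along one axis; gradient routed to the (first) arg-max."""
        idx = np.argmax(self.data, axis=axis)
        val = np.max(self.data, axis=axis, keepdims=keepdims)
        out = Tensor._make(val, (self,), None)

        def bwd(g):
            g = np.asarray(g)
            if keepdims:
                g = np.squeeze(g, axis=axis)
            full = np.zeros_like(self.data)
            np.put_along_axis(full, np.expand_dims(idx, axis),
                              np.expand_dims(g, axis), axis=axis)
            self._accum(full)
        out._backward = bwd
        return out

    # ------------------------------------------------------------------ shape
    def reshape(self, *shape):
        out = Tensor._make(self.data.reshape(*shape), (self,), None)

        def bwd(g):
            self._accum(np.asarray(g).reshape(self.data.shape))
        out._backward = bwd
        return out

    def transpose(self, *axes):
        out = Tensor._make(self.data.transpose(*axes), (self,), None)
        inv = np.argsort(axes)

        def bwd(g):
            self._accum(np.asarray(g).transpose(*inv))
        out._backward = bwd
        return out

    def __getitem__(self, idx):
        out = Tensor._make(self.data[idx], (self,), None)

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)
        out._backward = bwd
        return out

    # -------------------------------------------------------------- linear alg
    def nuclear_norm(self):
        """Sum of singular values; gradient is U @ V^T."""
        u, s, vt = np.linalg.svd(self.data, full_matrices=False)
        out = Tensor._make(s.sum(), (self,), None)

        def bwd(g):
            self._accum(float(g) * (u @ vt))
        out._backward = bwd
        return out

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=axis, keepdims=True)
        out = Tensor._make(p, (self,), None)

        def bwd(g):
            dot = (g * p).sum(axis=axis, keepdims=True)
            self._accum(p * (g - dot))
        out._backward = bwd
        return out

    def log_softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        ls = z - lse
        out = Tensor._make(ls, (self,), None)
        p = np.exp(ls)

        def bwd(g):
            self._accum(g - p * np.sum(g, axis=axis, keepdims=True))
        out._backward = bwd
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def minimum(a, b) -> Tensor:
    """Elementwise min; gradient routes to the smaller operand (ties: a)."""
    a, b = as_tensor(a), as_tensor(b)
    take_a = a.data <= b.data
    out = Tensor._make(np.where(take_a, a.data, b.data), (a, b), None)

    def bwd(g):
        g = np.asarray(g)
        if a.requires_grad:
            a._accum(g * take_a)
        if b.requires_grad:
            b._accum(g * ~take_a)
    out._backward = bwd
    return out


def maximum(a, b) -> Tensor:
    """Elementwise max; gradient routes to the larger operand (ties: a)."""
    a, b = as_tensor(a), as_tensor(b)
    take_a = a.data >= b.data
    out = Tensor._make(np.where(take_a, a.data, b.data), (a, b), None)

    def bwd(g):
        g = np.asarray(g)
        if a.requires_grad:
            a._accum(g * take_a)
        if b.requires_grad:
            b._accum(g * ~take_a)
    out._backward = bwd
    return out


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                       tensors, None)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        parts = np.split(np.asarray(g), splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accum(p)
    out._backward = bwd
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor._make(np.stack([t.data for t in tensors], axis=axis), tensors, None)

    def bwd(g):
        g = np.asarray(g)
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))
    out._backward = bwd
    return out
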