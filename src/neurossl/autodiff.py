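"""Small reverse-mode automatic differentiation engine over NumPy arrays.

The engine provides exactly the primitives the training objectives need:
broadcasting arithmetic, matmul, reductions, indexing, a numerically stable
logsumexp, plus the two gradient-flow control operators the objectives are
defined with — ``detach`` (stop-gradient) and ``grad_reverse`` (gradient
reversal for domain-adversarial training).  Gradients are accumulated in
float64 so finite-difference checks hold to tight tolerances.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concatenate", "stack", "grad_reverse", "no_grad"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_bw")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._bw = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, bw) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._bw = bw
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd core --------------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without argument requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(node: "Tensor"):
            stack = [(node, False)]
            while stack:
                n, done = stack.pop()
                if done:
                    topo.append(n)
                    continue
                if id(n) in seen or not n.requires_grad:
                    continue
                seen.add(id(n))
                stack.append((n, True))
                for p in n._parents:
                    stack.append((p, False))

        visit(self)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._bw is not None and node.grad is not None:
                node._bw(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor._make(out_data, (self, other), bw)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data**p

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1))

        return Tensor._make(out_data, (self,), bw)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bw)

    def sqrt(self):
        return self**0.5

    def relu(self):
        mask = self.data > 0

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor._make(self.data * mask, (self,), bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), bw)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def logsumexp(self, axis: int = -1, keepdims: bool = False):
        m = np.max(self.data, axis=axis, keepdims=True)
        e = np.exp(self.data - m)
        s = e.sum(axis=axis, keepdims=True)
        out_data = np.log(s) + m
        soft = e / s
        if not keepdims:
            out_data = np.squeeze(out_data, axis=axis)

        def bw(g):
            if self.requires_grad:
                gk = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(gk * soft)

        return Tensor._make(out_data, (self,), bw)

    # -- shape manipulation ---------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(orig))

        return Tensor._make(self.data.reshape(shape), (self,), bw)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), bw)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        return Tensor._make(out_data, (self,), bw)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), bw)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def bw(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(np.take(g, i, axis=axis))

    return Tensor._make(out_data, tuple(tensors), bw)


def grad_reverse(x: Tensor, strength: float = 1.0) -> Tensor:
    """Identity in the forward pass; scales gradients by ``-strength`` backward.

    This is the gradient-reversal layer used for domain-adversarial training:
    the discriminator downstream sees the embedding unchanged, while the
    encoder upstream receives the negated, scaled classification gradient.
    """
    x = as_tensor(x)
    if strength < 0:
        raise ValueError("grad_reverse strength must be non-negative")

    def bw(g):
        if x.requires_grad:
            x._accumulate(-strength * g)

    return Tensor._make(x.data.copy(), (x,), bw)
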