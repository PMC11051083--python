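"""Minimal reverse-mode autodiff on numpy arrays.

A small tensor/autograd core sized for this package: batched matmul,
broadcasting elementwise arithmetic, softmax, GELU and the indexing
operations the tokenizers and attention blocks need.  Gradients flow
through a dynamically built tape; ``no_grad`` disables taping for
inference.  float64 throughout so oracle comparisons are tight.
"""

from __future__ import annotations

import contextlib

import numpy as np
from scipy.special import erf

_GRAD_ENABLED = True
_DEFAULT_DTYPE = np.float64


@contextlib.contextmanager
def default_dtype(dtype):
    """Set the dtype newly created tensors are cast to (float32 halves the
    training footprint; float64 is the default for tight numerical checks)."""
    global _DEFAULT_DTYPE
    prev = _DEFAULT_DTYPE
    _DEFAULT_DTYPE = np.dtype(dtype)
    try:
        yield
    finally:
        _DEFAULT_DTYPE = prev


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the context (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_DEFAULT_DTYPE)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._prev: tuple = ()

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _result(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node)
            if node._prev:
                # free intermediate grads and tape references as soon as the
                # node has propagated, keeping peak memory near forward size
                node.grad = None
                node._backward = None
                node._prev = ()

    # -- shape info --------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other

        def bw(out):
            if a.requires_grad:
                a._accum(_unbroadcast(out.grad, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(out.grad, b.data.shape))

        return Tensor._result(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bw(out):
            if a.requires_grad:
                a._accum(-out.grad)

        return Tensor._result(-a.data, (a,), bw)

    def __sub__(self, other):
        return self + (-(other if isinstance(other, Tensor) else Tensor(other)))

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other

        def bw(out):
            if a.requires_grad:
                a._accum(_unbroadcast(out.grad * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(out.grad * a.data, b.data.shape))

        return Tensor._result(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return (other if isinstance(other, Tensor) else Tensor(other)) / self

    def __pow__(self, p: float):
        a = self

        def bw(out):
            if a.requires_grad:
                a._accum(out.grad * p * a.data ** (p - 1.0))

        return Tensor._result(a.data ** p, (a,), bw)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other

        def bw(out):
            g = out.grad
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.data.shape))

        return Tensor._result(a.data @ b.data, (a, b), bw)

    # -- reductions & reshaping -------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def bw(out):
            if not a.requires_grad:
                return
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.data.shape).copy())

        return Tensor._result(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        a = self

        def bw(out):
            if a.requires_grad:
                a._accum(out.grad.reshape(a.data.shape))

        return Tensor._result(a.data.reshape(*shape), (a,), bw)

    def transpose(self, *axes):
        a = self
        inv = np.argsort(axes)

        def bw(out):
            if a.requires_grad:
                a._accum(out.grad.transpose(*inv))

        return Tensor._result(a.data.transpose(*axes), (a,), bw)

    def swapaxes(self, ax1: int, ax2: int):
        a = self

        def bw(out):
            if a.requires_grad:
                a._accum(np.swapaxes(out.grad, ax1, ax2))

        return Tensor._result(np.swapaxes(a.data, ax1, ax2), (a,), bw)

    def __getitem__(self, idx):
        a = self

        def bw(out):
            if a.requires_grad:
                g = np.zeros_like(a.data)
                np.add.at(g, idx, out.grad)
                a._accum(g)

        return Tensor._result(a.data[idx], (a,), bw)

    # -- nonlinearities ----------------------------------------------------
    def exp(self):
        a = self
        val = np.exp(a.data)

        def bw(out):
            if a.requires_grad:
                a._accum(out.grad * out.data)

        return Tensor._result(val, (a,), bw)

    def log(self):
        a = self

        def bw(out):
            if a.requires_grad:
                a._accum(out.grad / a.data)

        return Tensor._result(np.log(a.data), (a,), bw)

    def tanh(self):
        a = self
        val = np.tanh(a.data)

        def bw(out):
            if a.requires_grad:
                a._accum(out.grad * (1.0 - out.data ** 2))

        return Tensor._result(val, (a,), bw)

    def relu(self):
        a = self

        def bw(out):
            if a.requires_grad:
                a._accum(out.grad * (a.data > 0))

        return Tensor._result(np.maximum(a.data, 0.0), (a,), bw)

    def gelu(self):
        """Exact Gaussian-error-linear unit, x * Phi(x)."""
        a = self
        x = a.data
        phi = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))

        def bw(out):
            if a.requires_grad:
                pdf = np.exp(-0.5 * x ** 2) / np.sqrt(2.0 * np.pi)
                a._accum(out.grad * (phi + x * pdf))

        return Tensor._result(x * phi, (a,), bw)

    def softmax(self, axis: int = -1):
        a = self
        z = a.data - a.data.max(axis=axis, keepdims=True)
        ez = np.exp(z)
        val = ez / ez.sum(axis=axis, keepdims=True)

        def bw(out):
            if a.requires_grad:
                y, g = out.data, out.grad
                a._accum(y * (g - (y * g).sum(axis=axis, keepdims=True)))

        return Tensor._result(val, (a,), bw)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize the last axis to zero mean / unit variance, then affine."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv

    def bw(out):
        g = out.grad
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=tuple(range(g.ndim - 1))))
        if beta.requires_grad:
            beta._accum(g.sum(axis=tuple(range(g.ndim - 1))))
        if x.requires_grad:
            gx = g * gamma.data
            n = x.data.shape[-1]
            x._accum(inv * (gx - gx.mean(axis=-1, keepdims=True)
                            - xhat * (gx * xhat).mean(axis=-1, keepdims=True)))

    return Tensor._result(xhat * gamma.data + beta.data, (x, gamma, beta), bw)


def cat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    parents = tuple(tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(out):
        for t, lo, hi in zip(parents, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out.grad.ndim
                sl[axis] = slice(lo, hi)
                t._accum(out.grad[tuple(sl)])

    return Tensor._result(np.concatenate([t.data for t in parents], axis=axis), parents, bw)


def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer ``targets`` given raw class ``logits``."""
    targets = np.asarray(targets, dtype=np.intp)
    z = logits.data
    zmax = z.max(axis=-1, keepdims=True)
    ez = np.exp(z - zmax)
    p = ez / ez.sum(axis=-1, keepdims=True)
    n = z.shape[0]
    loss = -np.mean(np.log(p[np.arange(n), targets]))

    def bw(out):
        if logits.requires_grad:
            g = p.copy()
            g[np.arange(n), targets] -= 1.0
            logits._accum(out.grad * g / n)

    return Tensor._result(loss, (logits,), bw)
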