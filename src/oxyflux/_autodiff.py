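"""Minimal reverse-mode automatic differentiation over numpy arrays.

The package deliberately runs on a small, dependency-free tensor engine:
the networks involved are tiny (a 1-D convolution, one LSTM layer, two
attention gates), so a hand-rolled reverse-mode graph over numpy keeps the
whole stack inspectable and exactly reproducible, bit for bit, on any CPU.

Only the primitives the models need are implemented: +, *, matmul, slicing,
concatenation, reductions (sum/mean/max), sigmoid/tanh/relu, and a
same-padded 1-D convolution.  Broadcasting follows numpy semantics; the
backward pass sums gradients over broadcast axes.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph: a float64 array plus its gradient."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = ()

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _child(self, data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        """Accumulate gradients of a scalar (or given seed) into the graph."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        for node in topo:
            node.grad = np.zeros_like(node.data)
        self.grad = np.asarray(grad, dtype=np.float64).reshape(self.data.shape)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g, other.data.shape)

        return self._child(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            if self.requires_grad:
                self.grad += -g

        return self._child(-self.data, (self,), bw)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * other.data, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g * self.data, other.data.shape)

        return self._child(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        return self * (1.0 / float(scalar))

    def __pow__(self, p):
        p = float(p)

        def bw(g):
            if self.requires_grad:
                self.grad += g * p * self.data ** (p - 1)

        return self._child(self.data ** p, (self,), bw)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            if self.requires_grad:
                self.grad += g @ other.data.T
            if other.requires_grad:
                other.grad += self.data.T @ g

        return self._child(self.data @ other.data, (self, other), bw)

    # -- shape ops ---------------------------------------------------------

    def __getitem__(self, idx):
        def bw(g):
            if self.requires_grad:
                np.add.at(self.grad, idx, g)

        return self._child(self.data[idx], (self,), bw)

    @property
    def T(self):
        if self.data.ndim != 2:
            raise ValueError("T is defined for 2-D tensors")

        def bw(g):
            if self.requires_grad:
                self.grad += g.T

        return self._child(self.data.T, (self,), bw)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self.grad += g.transpose(inv)

        return self._child(self.data.transpose(axes), (self,), bw)

    def reshape(self, *shape):
        old = self.data.shape

        def bw(g):
            if self.requires_grad:
                self.grad += g.reshape(old)

        return self._child(self.data.reshape(*shape), (self,), bw)

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self.grad += g  # g is scalar-shaped, broadcasts
            else:
                gexp = g if keepdims else np.expand_dims(g, axis)
                self.grad += np.broadcast_to(gexp, self.data.shape)

        return self._child(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def max(self, axis: int, keepdims=False):
        """Max along one axis; gradient flows to the first argmax (tie-break)."""
        idx = np.argmax(self.data, axis=axis)
        out = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis)

        def bw(g):
            if not self.requires_grad:
                return
            gexp = g if keepdims else np.expand_dims(g, axis)
            buf = np.zeros_like(self.data)
            np.put_along_axis(buf, np.expand_dims(idx, axis), gexp, axis=axis)
            self.grad += buf

        data = out if keepdims else np.squeeze(out, axis=axis)
        return self._child(data, (self,), bw)

    # -- nonlinearities ----------------------------------------------------

    def sigmoid(self):
        s = expit(self.data)

        def bw(g):
            if self.requires_grad:
                self.grad += g * s * (1.0 - s)

        return self._child(s, (self,), bw)

    def tanh(self):
        t = np.tanh(self.data)

        def bw(g):
            if self.requires_grad:
                self.grad += g * (1.0 - t * t)

        return self._child(t, (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            if self.requires_grad:
                self.grad += g * mask

        return self._child(self.data * mask, (self,), bw)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t.grad += g[tuple(sl)]

    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = bw
    return out


def conv1d_same(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Same-padded 1-D convolution (cross-correlation, conv-layer convention).

    x: (N, C_in, L); weight: (C_out, C_in, k) with k odd; bias: (C_out,).
    Returns (N, C_out, L).
    """
    xd, wd = x.data, weight.data
    n, c_in, length = xd.shape
    c_out, c_in_w, k = wd.shape
    if c_in != c_in_w:
        raise ValueError("channel mismatch between input and kernel")
    if k % 2 != 1:
        raise ValueError("kernel length must be odd for symmetric padding")
    pad = k // 2
    xp = np.pad(xd, ((0, 0), (0, 0), (pad, pad)))
    # im2col: (N, C_in*k, L)
    cols = np.stack([xp[:, :, j:j + length] for j in range(k)], axis=2)
    cols2 = cols.reshape(n, c_in * k, length)
    wmat = wd.reshape(c_out, c_in * k)
    out = np.einsum("oc,ncl->nol", wmat, cols2) + bias.data[None, :, None]

    def bw(g):
        if bias.requires_grad:
            bias.grad += g.sum(axis=(0, 2))
        if weight.requires_grad:
            gw = np.einsum("nol,ncl->oc", g, cols2)
            weight.grad += gw.reshape(c_out, c_in, k)
        if x.requires_grad:
            gcols = np.einsum("oc,nol->ncl", wmat, g).reshape(n, c_in, k, length)
            gxp = np.zeros_like(xp)
            for j in range(k):
                gxp[:, :, j:j + length] += gcols[:, :, j, :]
            x.grad += gxp[:, :, pad:pad + length]

    out_t = Tensor(out)
    if x.requires_grad or weight.requires_grad or bias.requires_grad:
        out_t.requires_grad = True
        out_t._parents = (x, weight, bias)
        out_t._backward = bw
    return out_t
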