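"""Reverse-mode automatic differentiation on NumPy arrays.

A deliberately small define-by-run tape: each operation returns a new
:class:`Tensor` carrying a closure that accumulates gradients into its
parents. Only the primitives needed by the segmentation network and the
autoencoder baseline are provided (elementwise arithmetic, reductions,
matmul, 3D convolution / transposed convolution, instance norm, PReLU,
sigmoid, concatenation, nearest upsampling).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "conv3d",
    "conv_transpose3d",
    "instance_norm",
    "prelu",
    "sigmoid",
    "upsample_nearest",
]


# Compute dtype for the whole engine. float32 keeps the 3D conv training
# loop within CPU budgets; tests that need tight numeric gradient checks
# switch this to float64.
DTYPE = np.float32


class Tensor:
    """An ndarray with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=()):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = tuple(_prev)

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self):
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()
        # break node<->closure reference cycles so graphs free promptly;
        # leaf tensors (parameters) keep their accumulated grads
        for t in topo:
            if t._prev:
                t._backward = None
                t._prev = ()
                t.grad = None

    def zero_grad(self):
        self.grad = None

    # -- elementwise arithmetic ------------------------------------------

    @staticmethod
    def _lift(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bwd():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bwd():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bwd():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-out.grad * self.data / other.data ** 2,
                                          other.data.shape))

        out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    # -- reductions / shaping --------------------------------------------

    def sum(self):
        out = Tensor(self.data.sum(), self.requires_grad, (self,))

        def bwd():
            if self.requires_grad:
                self._accum(np.full_like(self.data, out.grad))

        out._backward = bwd
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))

        def bwd():
            if self.requires_grad:
                self._accum(out.grad.reshape(self.data.shape))

        out._backward = bwd
        return out

    def matmul(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bwd():
            if self.requires_grad:
                self._accum(out.grad @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ out.grad)

        out._backward = bwd
        return out

    __matmul__ = matmul


def _unbroadcast(grad, shape):
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    g = grad
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def sigmoid(x: Tensor) -> Tensor:
    # numerically stable two-sided form
    s = np.where(x.data >= 0,
                 1.0 / (1.0 + np.exp(-np.clip(x.data, 0, None))),
                 np.exp(np.clip(x.data, None, 0))
                 / (1.0 + np.exp(np.clip(x.data, None, 0))))
    out = Tensor(s, x.requires_grad, (x,))

    def bwd():
        if x.requires_grad:
            x._accum(out.grad * s * (1.0 - s))

    out._backward = bwd
    return out


def prelu(x: Tensor, alpha: Tensor) -> Tensor:
    """Channel-wise PReLU; x is (C, D, H, W), alpha is (C,)."""
    a = alpha.data.reshape(-1, 1, 1, 1)
    pos = x.data > 0
    out = Tensor(np.where(pos, x.data, a * x.data),
                 x.requires_grad or alpha.requires_grad, (x, alpha))

    def bwd():
        if x.requires_grad:
            x._accum(np.where(pos, out.grad, a * out.grad))
        if alpha.requires_grad:
            alpha._accum(np.where(pos, 0.0, x.data * out.grad).sum(axis=(1, 2, 3)))

    out._backward = bwd
    return out


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-channel normalization over the spatial axes of a (C, D, H, W) field."""
    axes = (1, 2, 3)
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    g = gamma.data.reshape(-1, 1, 1, 1)
    out = Tensor(g * xhat + beta.data.reshape(-1, 1, 1, 1),
                 x.requires_grad or gamma.requires_grad or beta.requires_grad,
                 (x, gamma, beta))

    def bwd():
        go = out.grad
        if gamma.requires_grad:
            gamma._accum((go * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accum(go.sum(axis=axes))
        if x.requires_grad:
            n = x.data[0].size
            gx = go * g
            dxhat = gx
            dx = (dxhat - dxhat.mean(axis=axes, keepdims=True)
                  - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)) * inv
            del n
            x._accum(dx)

    out._backward = bwd
    return out


# -- 3D convolution via im2col -------------------------------------------


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """(C, D, H, W) -> (k^3*C, Do*Ho*Wo) patch matrix, offset-major.

    Offset-major layout keeps each destination block contiguous, which is
    what makes this loop fast; the weight matrix is permuted to match.
    """
    c = x.shape[0]
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (pad, pad)))
    _, d, h, w = x.shape
    do = (d - k) // stride + 1
    ho = (h - k) // stride + 1
    wo = (w - k) // stride + 1
    cols = np.empty((k, k, k, c, do, ho, wo), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            for l in range(k):
                cols[i, j, l] = x[:, i:i + do * stride:stride,
                                  j:j + ho * stride:stride,
                                  l:l + wo * stride:stride]
    return cols.reshape(k ** 3 * c, do * ho * wo), (do, ho, wo)


def _weight_as_matrix(w: np.ndarray) -> np.ndarray:
    """(Cout, Cin, k, k, k) -> (Cout, k^3*Cin) in the offset-major order."""
    cout = w.shape[0]
    return np.ascontiguousarray(w.transpose(2, 3, 4, 1, 0).reshape(-1, cout).T)


def _matrix_as_weight(m: np.ndarray, w_shape) -> np.ndarray:
    cout, cin, k, _, _ = w_shape
    return m.T.reshape(k, k, k, cin, cout).transpose(4, 3, 0, 1, 2)


def _col2im(cols: np.ndarray, x_shape, k: int, stride: int, pad: int, out_sp):
    """Scatter-add the offset-major patch matrix back onto the input grid."""
    c, d, h, w = x_shape
    do, ho, wo = out_sp
    xp = np.zeros((c, d + 2 * pad, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    cols = cols.reshape(k, k, k, c, do, ho, wo)
    for i in range(k):
        for j in range(k):
            for l in range(k):
                xp[:, i:i + do * stride:stride,
                   j:j + ho * stride:stride,
                   l:l + wo * stride:stride] += cols[i, j, l]
    if pad:
        return xp[:, pad:-pad, pad:-pad, pad:-pad]
    return xp


def conv3d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 1) -> Tensor:
    """x: (Cin, D, H, W); w: (Cout, Cin, k, k, k); b: (Cout,)."""
    cout, cin, k, _, _ = w.shape
    cols, out_sp = _im2col(x.data, k, stride, pad)
    wf = _weight_as_matrix(w.data)
    y = (wf @ cols + b.data[:, None]).reshape(cout, *out_sp)
    out = Tensor(y, x.requires_grad or w.requires_grad or b.requires_grad,
                 (x, w, b))

    def bwd():
        go = np.ascontiguousarray(out.grad.reshape(cout, -1))
        if b.requires_grad:
            b._accum(go.sum(axis=1))
        if w.requires_grad:
            w._accum(_matrix_as_weight(go @ cols.T, w.data.shape))
        if x.requires_grad:
            dcols = wf.T @ go
            x._accum(_col2im(dcols, x.data.shape, k, stride, pad, out_sp))

    out._backward = bwd
    return out


def conv_transpose3d(x: Tensor, w: Tensor, b: Tensor, stride: int = 2) -> Tensor:
    """Kernel-`stride`, stride-`stride` transposed conv (exact x`stride` upsampling).

    x: (Cin, D, H, W); w: (Cin, Cout, s, s, s); b: (Cout,).
    """
    s = stride
    cin, cout = w.shape[0], w.shape[1]
    _, d, h, wd = x.shape
    # (Cout, s, s, s, D, H, W)
    m = np.tensordot(w.data, x.data, axes=([0], [0]))
    y = m.transpose(0, 4, 1, 5, 2, 6, 3).reshape(cout, d * s, h * s, wd * s)
    y += b.data[:, None, None, None]
    out = Tensor(y, x.requires_grad or w.requires_grad or b.requires_grad,
                 (x, w, b))

    def bwd():
        go = out.grad.reshape(cout, d, s, h, s, wd, s).transpose(0, 2, 4, 6, 1, 3, 5)
        if b.requires_grad:
            b._accum(out.grad.sum(axis=(1, 2, 3)))
        if w.requires_grad:
            # dW[cin, cout, i, j, l] = sum_dhw x[cin,d,h,w] * go[cout,i,j,l,d,h,w]
            w._accum(np.tensordot(x.data, go, axes=([1, 2, 3], [4, 5, 6])))
        if x.requires_grad:
            x._accum(np.tensordot(w.data, go, axes=([1, 2, 3, 4], [0, 1, 2, 3])))

    out._backward = bwd
    return out


def upsample_nearest(x: Tensor, factor: int = 2) -> Tensor:
    f = factor
    y = x.data.repeat(f, axis=1).repeat(f, axis=2).repeat(f, axis=3)
    out = Tensor(y, x.requires_grad, (x,))

    def bwd():
        if x.requires_grad:
            c, d, h, w = x.shape
            g = out.grad.reshape(c, d, f, h, f, w, f).sum(axis=(2, 4, 6))
            x._accum(g)

    out._backward = bwd
    return out


def concat(tensors, axis: int = 0) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data, any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]

    def bwd():
        start = 0
        for t, n in zip(tensors, sizes):
            if t.requires_grad:
                idx = [slice(None)] * out.grad.ndim
                idx[axis] = slice(start, start + n)
                t._accum(out.grad[tuple(idx)])
            start += n

    out._backward = bwd
    return out
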