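"""Reverse-mode automatic differentiation on NumPy arrays.

A deliberately small tape-based engine: :class:`Tensor` wraps a float32
``numpy.ndarray`` and records, for every differentiable operation, a closure
that scatters the output gradient back to its parents.  The operation set is
exactly what a VGG-style convolutional classifier with channel/spatial
attention needs — broadcast arithmetic, matmul, ReLU/sigmooid/log/exp,
axis reductions (sum/mean/max), reshape/concat, 2-D convolution, 2×2 max
pooling, batch normalization and log-softmax.

Convolution is implemented as im2col + a single BLAS ``matmul``; the column
matrix is recomputed during the backward pass instead of being stored, which
halves peak memory at the price of one extra strided copy.

Gradients are accumulated on every node that requires them, including
intermediate activations — this is what lets Grad-CAM read ``tensor.grad``
of a feature map after a backward pass from a class score.
"""

from __future__ import annotations

from contextlib import contextmanager
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "concat",
    "conv2d",
    "max_pool2d",
    "batch_norm2d",
    "log_softmax",
]

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph construction (inference fast path)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _as_f32(x) -> np.ndarray:
    """Coerce to a float array: float32 by default, but float64 inputs are
    preserved (high-precision mode, used by gradient-check oracles)."""
    a = np.asarray(x)
    if a.dtype not in (np.float32, np.float64):
        a = a.astype(np.float32)
    return a


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce gradient ``g`` back to ``shape`` after NumPy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, (gs, ss) in enumerate(zip(g.shape, shape)):
        if ss == 1 and gs != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_f32(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    # -- basic properties ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic ----------------------------------------------------------
    def _coerce(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            return other
        arr = np.asarray(other)
        if arr.dtype != self.data.dtype:
            # scalars and mismatched operands follow this tensor's dtype so a
            # python float can never silently promote a float32 graph
            arr = arr.astype(self.data.dtype)
        return Tensor(arr)

    def __add__(self, other):
        other = self._coerce(other)
        out_data = self.data + other.data
        a, b = self, other

        def backward(out):
            g = out.grad
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._make(out_data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(out):
            a._accum(-out.grad)

        return Tensor._make(-self.data, (a,), backward)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        a, b = self, other
        out_data = a.data * b.data

        def backward(out):
            g = out.grad
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(out_data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise TypeError("tensor/tensor division is not part of the op set")
        return self * (1.0 / float(other))

    def __matmul__(self, other):
        other = self._coerce(other)
        a, b = self, other
        out_data = a.data @ b.data

        def backward(out):
            g = out.grad
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.data.shape))

        return Tensor._make(out_data, (a, b), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def relu(self):
        a = self
        out_data = np.maximum(a.data, 0.0)

        def backward(out):
            a._accum(out.grad * (a.data > 0))

        return Tensor._make(out_data, (a,), backward)

    def sigmoid(self):
        a = self
        s = 1.0 / (1.0 + np.exp(-a.data))

        def backward(out):
            a._accum(out.grad * s * (1.0 - s))

        return Tensor._make(s, (a,), backward)

    def log(self):
        a = self

        def backward(out):
            a._accum(out.grad / a.data)

        return Tensor._make(np.log(a.data), (a,), backward)

    def exp(self):
        a = self
        e = np.exp(a.data)

        def backward(out):
            a._accum(out.grad * e)

        return Tensor._make(e, (a,), backward)

    # -- reductions ------------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(out):
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.data.shape).astype(np.float32))

        return Tensor._make(out_data, (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[i] for i in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def amax(self, axis, keepdims: bool = False):
        """Max over ``axis``; ties share the gradient equally."""
        a = self
        axes = axis if isinstance(axis, tuple) else (axis,)
        mx = a.data.max(axis=axes, keepdims=True)

        def backward(out):
            g = out.grad
            if not keepdims:
                g = np.expand_dims(g, axes)
            mask = (a.data == mx).astype(np.float32)
            mask /= mask.sum(axis=axes, keepdims=True)
            a._accum(mask * g)

        out_data = mx if keepdims else np.squeeze(mx, axis=axes)
        return Tensor._make(out_data, (a,), backward)

    # -- shape ops --------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        orig = a.data.shape

        def backward(out):
            a._accum(out.grad.reshape(orig))

        return Tensor._make(a.data.reshape(shape), (a,), backward)

    # -- autodiff driver --------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that requires no grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("backward() without grad needs a scalar output")
            grad = np.ones_like(self.data)
        self.grad = _as_f32(grad).reshape(self.data.shape).copy()

        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))

        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node)


# -- multi-input / structured primitives ----------------------------------------

def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(out):
        g = out.grad
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    return Tensor._make(out_data, tensors, backward)


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(N, C, Hp, Wp) -> (N, C*kh*kw, OH*OW) column matrix (copies)."""
    n, c, hp, wp = xp.shape
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    sn, sc, sh, sw = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, c, kh, kw, oh, ow),
        strides=(sn, sc, sh, sw, sh * stride, sw * stride),
        writeable=False,
    )
    return view.reshape(n, c * kh * kw, oh * ow)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW layout, via im2col + BLAS matmul."""
    n, c, h, wd = x.data.shape
    oc, ic, kh, kw = w.data.shape
    if ic != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight expects {ic}")
    p = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    oh = (h + 2 * p - kh) // stride + 1
    ow = (wd + 2 * p - kw) // stride + 1
    cols = _im2col(xp, kh, kw, stride)
    out_data = np.matmul(w.data.reshape(oc, -1), cols).reshape(n, oc, oh, ow)
    if b is not None:
        out_data += b.data.reshape(1, oc, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(out):
        g = out.grad.reshape(n, oc, oh * ow)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2)))
        if w.requires_grad:
            cols_b = _im2col(xp, kh, kw, stride)
            gw = np.matmul(g, np.swapaxes(cols_b, 1, 2)).sum(axis=0)
            w._accum(gw.reshape(w.data.shape))
        if x.requires_grad:
            dcols = np.matmul(w.data.reshape(oc, -1).T, g)
            dcols = dcols.reshape(n, c, kh, kw, oh, ow)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + oh * stride:stride,
                        j:j + ow * stride:stride] += dcols[:, :, i, j]
            x._accum(dxp[:, :, p:p + h, p:p + wd] if p else dxp)

    return Tensor._make(out_data, parents, backward)


def max_pool2d(x: Tensor, kernel: int = 2, stride: int | None = None) -> Tensor:
    """Non-overlapping max pooling (kernel == stride); trailing rows/cols
    that do not fill a window are dropped (floor semantics)."""
    if stride is None:
        stride = kernel
    if stride != kernel:
        raise ValueError("only kernel == stride pooling is supported")
    n, c, h, w = x.data.shape
    oh, ow = h // kernel, w // kernel
    h2, w2 = oh * kernel, ow * kernel
    xc = x.data[:, :, :h2, :w2].reshape(n, c, oh, kernel, ow, kernel)
    out_data = xc.max(axis=(3, 5))

    def backward(out):
        mask = (xc == out_data[:, :, :, None, :, None]).astype(np.float32)
        mask /= mask.sum(axis=(3, 5), keepdims=True)
        g = mask * out.grad[:, :, :, None, :, None]
        dx = np.zeros_like(x.data)
        dx[:, :, :h2, :w2] = g.reshape(n, c, h2, w2)
        x._accum(dx)

    return Tensor._make(out_data, (x,), backward)


def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                 running_mean: np.ndarray, running_var: np.ndarray,
                 training: bool, momentum: float = 0.1,
                 eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization over (N, H, W).

    In training mode the batch statistics normalize and the running buffers
    are updated in place (unbiased variance, as is conventional); in eval
    mode the running buffers normalize and the op is a per-channel affine map.
    """
    n, c, h, w = x.data.shape
    if training:
        m = n * h * w
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= (1.0 - momentum)
        running_mean += momentum * mu
        running_var *= (1.0 - momentum)
        running_var += momentum * (var * (m / max(m - 1, 1)))
        invstd = 1.0 / np.sqrt(var + eps)
        xhat = (x.data - mu.reshape(1, c, 1, 1)) * invstd.reshape(1, c, 1, 1)
        out_data = gamma.data.reshape(1, c, 1, 1) * xhat + beta.data.reshape(1, c, 1, 1)

        def backward(out):
            g = out.grad
            if beta.requires_grad:
                beta._accum(g.sum(axis=(0, 2, 3)))
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
            if x.requires_grad:
                dxhat = g * gamma.data.reshape(1, c, 1, 1)
                s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
                s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
                dx = (invstd.reshape(1, c, 1, 1) / m) * (m * dxhat - s1 - xhat * s2)
                x._accum(dx.astype(x.data.dtype))

        return Tensor._make(out_data, (x, gamma, beta), backward)

    invstd = (1.0 / np.sqrt(running_var + eps)).astype(np.float32)
    scale = (gamma.data * invstd).reshape(1, c, 1, 1)
    shift = (beta.data - gamma.data * running_mean * invstd).reshape(1, c, 1, 1)
    out_data = x.data * scale + shift

    def backward_eval(out):
        g = out.grad
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3)))
        if gamma.requires_grad:
            xhat = (x.data - running_mean.reshape(1, c, 1, 1)) * invstd.reshape(1, c, 1, 1)
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        if x.requires_grad:
            x._accum(g * scale)

    return Tensor._make(out_data, (x, gamma, beta), backward_eval)


def log_softmax(x: Tensor, axis: int = 1) -> Tensor:
    a = x
    mx = a.data.max(axis=axis, keepdims=True)
    z = a.data - mx
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    ls = z - lse

    def backward(out):
        g = out.grad
        a._accum(g - np.exp(ls) * g.sum(axis=axis, keepdims=True))

    return Tensor._make(ls, (a,), backward)
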