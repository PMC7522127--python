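"""Minimal reverse-mode autodiff on numpy arrays.

A :class:`Tensor` wraps an ndarray and records the operations applied to it
so that gradients of a scalar objective with respect to every
``requires_grad`` leaf can be obtained with one call to
:meth:`Tensor.backward`.  The op set is intentionally small: exactly what the
segmentation networks and compound losses in this package need (elementwise
arithmetic, reductions, sigmoid/relu/log/abs/clip, channel concatenation,
N-dimensional convolution with stride/dilation, depthwise convolution,
2x max pooling and 2x nearest-neighbour upsampling).

dtype is preserved: float32 graphs stay float32 (network training), float64
graphs stay float64 (metric/loss evaluation at full precision).
"""

from __future__ import annotations

import itertools
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "conv_nd",
    "conv_depthwise2d",
    "maxpool2d",
    "upsample_nearest",
]


def _accumulate(t: "Tensor", g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = g.astype(t.data.dtype, copy=True)
    else:
        t.grad += g


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast from ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make ndarray <op> Tensor dispatch to the reflected Tensor methods
    # instead of numpy broadcasting the Tensor as an object scalar
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float64)
        self.data = arr
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helper used by every op -------------------------------
    @staticmethod
    def _op(data: np.ndarray, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor.__new__(Tensor)
        out.data = data
        out.grad = None
        out._parents = tuple(parents)
        out.requires_grad = any(p.requires_grad for p in parents)
        out._backward = backward if out.requires_grad else None
        return out

    # -- basic protocol ------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autodiff ------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient "
                                 "requires a scalar output")
            grad = np.ones_like(self.data)
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
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node._parents:
                # intermediate node: release its gradient and detach it so
                # the graph frees eagerly by reference counting
                node.grad = None
                node._backward = None
                node._parents = ()

    def zero_grad(self) -> None:
        self.grad = None

    def _coerce(self, other) -> "Tensor":
        """Wrap ``other`` as a Tensor; scalars adopt this tensor's dtype so
        float32 graphs are not silently upcast to float64."""
        if isinstance(other, Tensor):
            return other
        if np.isscalar(other):
            return Tensor(np.asarray(other, dtype=self.data.dtype))
        return Tensor(other)

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other):
        other = self._coerce(other)
        a, b = self, other
        out = Tensor._op(a.data + b.data, (a, b), None)

        def backward(g):
            _accumulate(a, _unbroadcast(g, a.shape))
            _accumulate(b, _unbroadcast(g, b.shape))

        out._backward = backward if out.requires_grad else None
        return out

    __radd__ = __add__

    def __neg__(self):
        a = self
        out = Tensor._op(-a.data, (a,), None)
        out._backward = (lambda g: _accumulate(a, -g)) if out.requires_grad else None
        return out

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        a, b = self, other
        out = Tensor._op(a.data * b.data, (a, b), None)

        def backward(g):
            _accumulate(a, _unbroadcast(g * b.data, a.shape))
            _accumulate(b, _unbroadcast(g * a.data, b.shape))

        out._backward = backward if out.requires_grad else None
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        a, b = self, other
        out = Tensor._op(a.data / b.data, (a, b), None)

        def backward(g):
            _accumulate(a, _unbroadcast(g / b.data, a.shape))
            _accumulate(b, _unbroadcast(-g * a.data / (b.data * b.data), b.shape))

        out._backward = backward if out.requires_grad else None
        return out

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def pow(self, p: float):
        a = self
        out = Tensor._op(a.data ** p, (a,), None)

        def backward(g):
            _accumulate(a, g * p * a.data ** (p - 1))

        out._backward = backward if out.requires_grad else None
        return out

    __pow__ = pow

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)
        out = Tensor._op(np.asarray(out_data), (a,), None)

        def backward(g):
            if axis is None:
                _accumulate(a, np.broadcast_to(g, a.shape).copy())
                return
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            gg = g
            if not keepdims:
                for ax in sorted(ax % a.ndim for ax in axes):
                    gg = np.expand_dims(gg, ax)
            _accumulate(a, np.broadcast_to(gg, a.shape).copy())

        out._backward = backward if out.requires_grad else None
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # -- elementwise nonlinearities ------------------------------------------
    def log(self):
        a = self
        out = Tensor._op(np.log(a.data), (a,), None)
        out._backward = (lambda g: _accumulate(a, g / a.data)) if out.requires_grad else None
        return out

    def exp(self):
        a = self
        e = np.exp(a.data)
        out = Tensor._op(e, (a,), None)
        out._backward = (lambda g: _accumulate(a, g * e)) if out.requires_grad else None
        return out

    def abs(self):
        a = self
        out = Tensor._op(np.abs(a.data), (a,), None)
        out._backward = (lambda g: _accumulate(a, g * np.sign(a.data))) if out.requires_grad else None
        return out

    def relu(self):
        a = self
        out = Tensor._op(np.maximum(a.data, 0), (a,), None)
        out._backward = (lambda g: _accumulate(a, g * (a.data > 0))) if out.requires_grad else None
        return out

    def sigmoid(self):
        a = self
        with np.errstate(over="ignore"):
            s = 1.0 / (1.0 + np.exp(-a.data))
        s = s.astype(a.data.dtype)
        out = Tensor._op(s, (a,), None)
        out._backward = (lambda g: _accumulate(a, g * s * (1 - s))) if out.requires_grad else None
        return out

    def clip(self, lo: float, hi: float):
        a = self
        out = Tensor._op(np.clip(a.data, lo, hi), (a,), None)

        def backward(g):
            mask = (a.data >= lo) & (a.data <= hi)
            _accumulate(a, g * mask)

        out._backward = backward if out.requires_grad else None
        return out

    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor._op(a.data.reshape(shape), (a,), None)
        out._backward = (lambda g: _accumulate(a, g.reshape(a.shape))) if out.requires_grad else None
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    out = Tensor._op(np.concatenate([t.data for t in ts], axis=axis), ts, None)
    sizes = [t.shape[axis] for t in ts]

    def backward(g):
        offset = 0
        for t, s in zip(ts, sizes):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(offset, offset + s)
            _accumulate(t, g[tuple(sl)])
            offset += s

    out._backward = backward if out.requires_grad else None
    return out


# ---------------------------------------------------------------------------
# Convolution primitives ("same" padding; output spatial = ceil(in/stride))
# ---------------------------------------------------------------------------

def _conv_geometry(spatial, kernel, stride, dilation):
    out_shape = tuple(-(-s // st) for s, st in zip(spatial, stride))
    eff = tuple((k - 1) * d + 1 for k, d in zip(kernel, dilation))
    pad_lo, pad_hi = [], []
    for s, o, st, e in zip(spatial, out_shape, stride, eff):
        total = max((o - 1) * st + e - s, 0)
        pad_lo.append(total // 2)
        pad_hi.append(total - total // 2)
    return out_shape, tuple(pad_lo), tuple(pad_hi)


def _tap_slices(offsets, dilation, stride, out_shape):
    return tuple(
        slice(o * d, o * d + st * (osz - 1) + 1, st)
        for o, d, st, osz in zip(offsets, dilation, stride, out_shape)
    )


def _normalize(v, nd):
    return (v,) * nd if isinstance(v, int) else tuple(v)


def conv_nd(x: Tensor, w: Tensor, b: Tensor | None = None,
            stride: int | tuple = 1, dilation: int | tuple = 1) -> Tensor:
    """Full (cross-channel) convolution over 2 or 3 spatial dims.

    ``x``: (N, Cin, \\*S); ``w``: (Cout, Cin, \\*K); ``b``: (Cout,).
    """
    x = as_tensor(x)
    w = as_tensor(w)
    nd = x.ndim - 2
    kernel = w.shape[2:]
    stride = _normalize(stride, nd)
    dilation = _normalize(dilation, nd)
    n, cin = x.shape[:2]
    cout = w.shape[0]
    spatial = x.shape[2:]
    out_shape, pad_lo, pad_hi = _conv_geometry(spatial, kernel, stride, dilation)
    xp = np.pad(x.data, [(0, 0), (0, 0)] + list(zip(pad_lo, pad_hi)))
    taps = list(itertools.product(*[range(k) for k in kernel]))
    ntap = len(taps)
    w2 = w.data.reshape(cout, cin, ntap)
    m = int(np.prod(out_shape))

    acc = np.zeros((n, cout, m), dtype=x.dtype)
    for t, offs in enumerate(taps):
        sl = _tap_slices(offs, dilation, stride, out_shape)
        xt = np.ascontiguousarray(
            xp[(slice(None), slice(None)) + sl]).reshape(n, cin, m)
        acc += np.matmul(w2[:, :, t], xt)   # (cout,cin) @ (n,cin,m) -> BLAS
    out_data = acc.reshape((n, cout) + out_shape)
    if b is not None:
        b = as_tensor(b)
        out_data = out_data + b.data.reshape((1, cout) + (1,) * nd)

    parents = (x, w) if b is None else (x, w, b)
    out = Tensor._op(out_data, parents, None)

    def backward(g):
        g2 = g.reshape(n, cout, m)
        if b is not None and b.requires_grad:
            _accumulate(b, g.sum(axis=(0,) + tuple(range(2, g.ndim))))
        need_x = x.requires_grad
        need_w = w.requires_grad
        gxp = np.zeros_like(xp) if need_x else None
        gw = np.zeros_like(w2) if need_w else None
        for t, offs in enumerate(taps):
            sl = _tap_slices(offs, dilation, stride, out_shape)
            idx = (slice(None), slice(None)) + sl
            if need_w:
                xt = np.ascontiguousarray(xp[idx]).reshape(n, cin, m)
                # sum_n g2[n] @ xt[n].T
                gw[:, :, t] = np.matmul(g2, xt.transpose(0, 2, 1)).sum(axis=0)
            if need_x:
                gx_t = np.matmul(w2[:, :, t].T, g2)  # (cin,cout) @ (n,cout,m)
                gxp[idx] += gx_t.reshape((n, cin) + out_shape)
        if need_w:
            _accumulate(w, gw.reshape(w.shape))
        if need_x:
            crop = (slice(None), slice(None)) + tuple(
                slice(lo, lo + s) for lo, s in zip(pad_lo, spatial))
            _accumulate(x, gxp[crop])

    out._backward = backward if out.requires_grad else None
    return out


def conv_depthwise2d(x: Tensor, w: Tensor, dilation: int = 1) -> Tensor:
    """Per-channel (depthwise) 2D convolution.

    ``x``: (N, C, H, W); ``w``: (C, kh, kw). Stride 1, "same" padding.
    """
    x = as_tensor(x)
    w = as_tensor(w)
    n, c, h, ww_ = x.shape
    kernel = w.shape[1:]
    dil = (dilation, dilation)
    out_shape, pad_lo, pad_hi = _conv_geometry((h, ww_), kernel, (1, 1), dil)
    xp = np.pad(x.data, [(0, 0), (0, 0)] + list(zip(pad_lo, pad_hi)))
    taps = list(itertools.product(range(kernel[0]), range(kernel[1])))
    ntap = len(taps)
    w2 = w.data.reshape(c, ntap)

    from . import _kernels

    use_numba = _kernels.HAVE_NUMBA and x.dtype == w.dtype
    if use_numba:
        acc = np.empty((n, c) + out_shape, dtype=x.dtype)
        _kernels.dw2d_forward(xp, w2, kernel[0], kernel[1], dilation, acc)
    else:
        acc = np.zeros((n, c) + out_shape, dtype=x.dtype)
        buf = np.empty_like(acc)
        for t, offs in enumerate(taps):
            sl = (slice(None), slice(None)) + _tap_slices(offs, dil, (1, 1),
                                                          out_shape)
            np.multiply(xp[sl], w2[:, t].reshape(1, c, 1, 1), out=buf)
            acc += buf
    out = Tensor._op(acc, (x, w), None)

    def backward(g):
        need_x = x.requires_grad
        need_w = w.requires_grad
        gxp = np.zeros_like(xp) if need_x else None
        gw = np.zeros_like(w2) if need_w else None
        if use_numba and g.dtype == xp.dtype:
            dummy = np.empty((0, 0), dtype=xp.dtype)
            _kernels.dw2d_backward(
                np.ascontiguousarray(g), xp, w2, kernel[0], kernel[1], dilation,
                gxp if need_x else np.empty((0, 0, 0, 0), dtype=xp.dtype),
                gw if need_w else dummy, need_x, need_w)
        else:
            tmp = np.empty_like(g)
            for t, offs in enumerate(taps):
                sl = (slice(None), slice(None)) + _tap_slices(offs, dil, (1, 1),
                                                              out_shape)
                if need_w:
                    np.multiply(g, xp[sl], out=tmp)
                    gw[:, t] = tmp.sum(axis=(0, 2, 3))
                if need_x:
                    np.multiply(g, w2[:, t].reshape(1, c, 1, 1), out=tmp)
                    gxp[sl] += tmp
        if need_w:
            _accumulate(w, gw.reshape(w.shape))
        if need_x:
            crop = (slice(None), slice(None)) + tuple(
                slice(lo, lo + s) for lo, s in zip(pad_lo, (h, ww_)))
            _accumulate(x, gxp[crop])

    out._backward = backward if out.requires_grad else None
    return out


def maxpool2d(x: Tensor) -> Tensor:
    """2x2 max pooling; spatial dims must be even."""
    x = as_tensor(x)
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2d requires even spatial dims, got {(h, w)}")
    blocks = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    blocks = blocks.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    idx = blocks.argmax(axis=-1)
    out = Tensor._op(np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0], (x,), None)

    def backward(g):
        gb = np.zeros((n, c, h // 2, w // 2, 4), dtype=g.dtype)
        np.put_along_axis(gb, idx[..., None], g[..., None], axis=-1)
        gb = gb.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        _accumulate(x, gb.reshape(n, c, h, w))

    out._backward = backward if out.requires_grad else None
    return out


def upsample_nearest(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling over all spatial dims (2D or 3D)."""
    x = as_tensor(x)
    nd = x.ndim - 2
    data = x.data
    for ax in range(2, 2 + nd):
        data = np.repeat(data, 2, axis=ax)
    out = Tensor._op(data, (x,), None)

    def backward(g):
        lead = g.shape[:2]
        shp: list[int] = list(lead)
        for s in x.shape[2:]:
            shp += [s, 2]
        gg = g.reshape(shp)
        axes = tuple(3 + 2 * i for i in range(nd))
        _accumulate(x, gg.sum(axis=axes))

    out._backward = backward if out.requires_grad else None
    return out
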