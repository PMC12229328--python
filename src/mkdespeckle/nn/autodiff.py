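"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small engine: a :class:`Tensor` wraps an ``ndarray`` and
records the backward closure of each primitive op.  The op set is exactly
what the despeckling networks and their composite loss need — elementwise
arithmetic, reductions, reshapes, 2-D convolution (stride 1, zero padding),
2×2 max-pooling, nearest-neighbour 2× upsampling and concatenation.

Image batches use channels-last ``(N, H, W, C)`` layout, which keeps the
im2col gather of the convolution cache-friendly.  Tensors preserve their
floating dtype: networks train in float32 for speed, while float64 inputs
(used wherever tight numerical agreement with closed forms is asserted)
stay float64 end to end.  Gradients are accumulated, so a node used twice
receives the sum of both paths.  ``no_grad()`` disables graph recording
for inference.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager that disables graph construction."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the reverse of numpy broadcasting)."""
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
    """A numpy array with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _coerce(self, other) -> "Tensor":
        """Wrap scalars in the dtype of ``self`` so float32 graphs stay float32."""
        if isinstance(other, Tensor):
            return other
        if np.isscalar(other):
            return Tensor(np.asarray(other, dtype=self.data.dtype))
        return Tensor(other)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph plumbing -------------------------------------------------------

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    @staticmethod
    def _make(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        a, b = self, self._coerce(other)
        out_data = a.data + b.data

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.shape))

        return Tensor._make(out_data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            a._accumulate(-g)

        return Tensor._make(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        a, b = self, self._coerce(other)
        out_data = a.data * b.data

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(out_data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, self._coerce(other)
        out_data = a.data / b.data

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / (b.data ** 2), b.shape))

        return Tensor._make(out_data, (a, b), backward)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        a = self
        out_data = a.data ** exponent

        def backward(g):
            a._accumulate(g * exponent * a.data ** (exponent - 1))

        return Tensor._make(out_data, (a,), backward)

    def __matmul__(self, other):
        a, b = self, Tensor.as_tensor(other)
        out_data = a.data @ b.data

        def backward(g):
            if a.requires_grad:
                a._accumulate(g @ np.swapaxes(b.data, -1, -2))
            if b.requires_grad:
                b._accumulate(np.swapaxes(a.data, -1, -2) @ g)

        return Tensor._make(out_data, (a, b), backward)

    # -- elementwise functions ------------------------------------------------

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            a._accumulate(g * out_data)

        return Tensor._make(out_data, (a,), backward)

    def log(self):
        a = self
        out_data = np.log(a.data)

        def backward(g):
            a._accumulate(g / a.data)

        return Tensor._make(out_data, (a,), backward)

    def sqrt(self):
        return self ** 0.5

    def abs(self):
        a = self
        out_data = np.abs(a.data)

        def backward(g):
            a._accumulate(g * np.sign(a.data))

        return Tensor._make(out_data, (a,), backward)

    def leaky_relu(self, negative_slope: float = 0.2):
        a = self
        mask = a.data > 0
        out_data = np.where(mask, a.data, np.asarray(negative_slope, dtype=a.data.dtype) * a.data)

        def backward(g):
            slope = np.asarray(negative_slope, dtype=a.data.dtype)
            a._accumulate(g * np.where(mask, np.asarray(1.0, dtype=a.data.dtype), slope))

        return Tensor._make(out_data, (a,), backward)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.shape))

        return Tensor._make(out_data, (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            n = int(np.prod([self.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max_detached(self, axis=None, keepdims: bool = False) -> np.ndarray:
        """Max of the underlying data, outside the graph (softmax shift)."""
        return self.data.max(axis=axis, keepdims=keepdims)

    # -- shape ops ------------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        out_data = a.data.reshape(shape)

        def backward(g):
            a._accumulate(g.reshape(a.shape))

        return Tensor._make(out_data, (a,), backward)

    def transpose(self, axes: Sequence[int]):
        a = self
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))
        out_data = a.data.transpose(axes)

        def backward(g):
            a._accumulate(g.transpose(inv))

        return Tensor._make(out_data, (a,), backward)

    def __getitem__(self, idx):
        a = self
        out_data = a.data[idx]

        def backward(g):
            buf = np.zeros_like(a.data)
            np.add.at(buf, idx, g)
            a._accumulate(buf)

        return Tensor._make(out_data, (a,), backward)


# -- multi-input / structured ops ---------------------------------------------


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    ts = [Tensor.as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    ax = axis if axis >= 0 else out_data.ndim + axis
    sizes = [t.shape[ax] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[ax] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(out_data, ts, backward)


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """View an (N, H, W, C) array as (N*Ho*Wo, kh*kw*C) patch columns."""
    n, h, w, c = x.shape
    ho, wo = h - kh + 1, w - kw + 1
    s0, s1, s2, s3 = x.strides
    view = np.lib.stride_tricks.as_strided(
        x, shape=(n, ho, wo, kh, kw, c), strides=(s0, s1, s2, s1, s2, s3)
    )
    return view.reshape(n * ho * wo, kh * kw * c)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), stride 1, zero padding.

    ``x``: (N, H, W, C); ``weight``: (kh, kw, C, F); ``bias``: (F,) or None.
    """
    x = Tensor.as_tensor(x)
    n, h, w, c = x.shape
    kh, kw, c_w, f = weight.shape
    if c != c_w:
        raise ValueError(f"channel mismatch: input has {c}, weight expects {c_w}")
    if padding:
        xp = np.pad(x.data, ((0, 0), (padding, padding), (padding, padding), (0, 0)))
    else:
        xp = x.data
    ho, wo = xp.shape[1] - kh + 1, xp.shape[2] - kw + 1
    cols = _im2col(xp, kh, kw)                      # (N*Ho*Wo, K)
    w2 = weight.data.reshape(kh * kw * c, f)        # (K, F)
    out_data = cols @ w2                            # (N*Ho*Wo, F)
    if bias is not None:
        out_data = out_data + bias.data
    out_data = out_data.reshape(n, ho, wo, f)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        # shift-accumulate form: one small matmul per kernel offset keeps
        # every gather/scatter row-contiguous, which im2col's transpose-heavy
        # col2im is not
        g2 = g.reshape(n * ho * wo, f)
        wk = weight.data.reshape(kh, kw, c, f)
        need_dw = weight.requires_grad
        need_dx = x.requires_grad
        if need_dw:
            dw = np.empty_like(wk)
        if need_dx:
            dxp = np.zeros_like(xp)
        if need_dw or need_dx:
            for u in range(kh):
                for v in range(kw):
                    if need_dw:
                        xs = xp[:, u:u + ho, v:v + wo, :].reshape(n * ho * wo, c)
                        dw[u, v] = xs.T @ g2
                    if need_dx:
                        dxp[:, u:u + ho, v:v + wo, :] += \
                            (g2 @ wk[u, v].T).reshape(n, ho, wo, c)
        if need_dw:
            weight._accumulate(dw.reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g2.sum(axis=0))
        if need_dx:
            if padding:
                dxp = dxp[:, padding:-padding, padding:-padding, :]
            x._accumulate(dxp)

    return Tensor._make(out_data, parents, backward)


def max_pool2d(x: Tensor, size: int = 2) -> Tensor:
    """Non-overlapping max pooling; spatial dims must divide ``size``."""
    x = Tensor.as_tensor(x)
    n, h, w, c = x.shape
    if h % size or w % size:
        raise ValueError(f"spatial dims ({h}, {w}) not divisible by pool size {size}")
    xr = x.data.reshape(n, h // size, size, w // size, size, c)
    out_data = xr.max(axis=(2, 4))

    def backward(g):
        m = out_data[:, :, None, :, None, :]
        mask = (xr == m).astype(x.data.dtype)
        counts = mask.sum(axis=(2, 4), keepdims=True)
        gx = (mask / counts) * g[:, :, None, :, None, :]
        x._accumulate(gx.reshape(x.shape))

    return Tensor._make(out_data, (x,), backward)


def upsample_nearest2d(x: Tensor, scale: int = 2) -> Tensor:
    x = Tensor.as_tensor(x)
    n, h, w, c = x.shape
    out_data = np.repeat(np.repeat(x.data, scale, axis=1), scale, axis=2)

    def backward(g):
        gr = g.reshape(n, h, scale, w, scale, c).sum(axis=(2, 4))
        x._accumulate(gr)

    return Tensor._make(out_data, (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along ``axis`` (shift is detached)."""
    shift = x.max_detached(axis=axis, keepdims=True)
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)
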