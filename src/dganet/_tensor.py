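"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Every learnable block in this package is built from the primitives here.
Arrays are kept in float64 so the oracle comparisons in the test-suite
(1e-5 .. 1e-9 tolerances) are not limited by single precision.
"""

from __future__ import annotations

import contextlib
import math
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import special

__all__ = [
    "Tensor",
    "concat",
    "chunk",
    "conv2d",
    "maxpool2x2",
    "avgpool2x2",
    "resize_bilinear",
    "upsample2x",
    "fft2",
    "ifft2",
    "softmax",
    "count_macs_context",
    "mac_count",
]

# ---------------------------------------------------------------------------
# MAC instrumentation (multiply-accumulate counting for conv/matmul ops)
# ---------------------------------------------------------------------------

_MACS = {"active": False, "count": 0}


@contextlib.contextmanager
def count_macs_context():
    """Count multiply-accumulates of conv2d/matmul ops executed inside."""
    prev = (_MACS["active"], _MACS["count"])
    _MACS["active"], _MACS["count"] = True, 0
    holder = {"count": 0}
    try:
        yield holder
    finally:
        holder["count"] = _MACS["count"]
        _MACS["active"], _MACS["count"] = prev


def mac_count() -> int:
    return _MACS["count"]


def _add_macs(n: int) -> None:
    if _MACS["active"]:
        _MACS["count"] += int(n)


# ---------------------------------------------------------------------------
# Core tensor
# ---------------------------------------------------------------------------


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray plus the closure needed to backpropagate through it."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    # -- bookkeeping ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            g = np.asarray(g, dtype=np.float64)
            # own the buffer only if the incoming gradient aliases other storage
            self.grad = g if g.base is None and g.flags.owndata else g.copy()
        else:
            self.grad = self.grad + g

    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs here can be a few thousand nodes deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.ones_like(self.data) if grad is None else grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic ---------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        out_data = np.matmul(self.data, other.data)
        n, k = self.data.shape[-2], self.data.shape[-1]
        m = other.data.shape[-1]
        _add_macs(int(np.prod(out_data.shape[:-2], dtype=np.int64)) * n * k * m)

        def backward(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                a = self.data
                if a.ndim == 1:
                    a = a[None, :]
                gb = np.matmul(np.swapaxes(a, -1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    # -- pointwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(out_data, (self,), backward)

    def clip_min(self, lo: float):
        mask = self.data > lo
        out_data = np.where(mask, self.data, lo)

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def leaky_relu(self, negative_slope: float = 0.01):
        factor = np.where(self.data > 0, 1.0, negative_slope)

        def backward(g):
            if self.requires_grad:
                self._accum(g * factor)

        return Tensor._make(self.data * factor, (self,), backward)

    def gelu(self):
        # exact Gaussian form: x * Phi(x)
        x = self.data
        phi = 0.5 * (1.0 + special.erf(x / math.sqrt(2.0)))
        pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (phi + x * pdf))

        return Tensor._make(x * phi, (self,), backward)

    # -- reductions / reshapes ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape))

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(src))

        return Tensor._make(out_data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def slice(self, index):
        out_data = self.data[index]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[index] = g
                self._accum(full)

        return Tensor._make(out_data, (self,), backward)


# ---------------------------------------------------------------------------
# Structural ops
# ---------------------------------------------------------------------------


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    return Tensor._make(out_data, tuple(tensors), backward)


def chunk(x: Tensor, n: int, axis: int = 1) -> list[Tensor]:
    size = x.data.shape[axis]
    if size % n != 0:
        raise ValueError(f"axis of length {size} not divisible into {n} chunks")
    step = size // n
    out = []
    for i in range(n):
        idx = [slice(None)] * x.data.ndim
        idx[axis] = slice(i * step, (i + 1) * step)
        out.append(x.slice(tuple(idx)))
    return out


# ---------------------------------------------------------------------------
# Convolution and pooling
# ---------------------------------------------------------------------------


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 0, dilation: int = 1) -> Tensor:
    """2-D cross-correlation over (B, C, H, W) input with (O, C, kh, kw) kernel."""
    xd, wd = x.data, w.data
    if xd.ndim != 4 or wd.ndim != 4:
        raise ValueError("conv2d expects 4-D input and kernel")
    B, C, H, W = xd.shape
    O, Ci, kh, kw = wd.shape
    if Ci != C:
        raise ValueError(f"channel mismatch: input has {C} channels, kernel expects {Ci}")
    xp = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding))) if padding else xd
    eh, ew = (kh - 1) * dilation + 1, (kw - 1) * dilation + 1
    Hp, Wp = xp.shape[2:]
    if Hp < eh or Wp < ew:
        raise ValueError("input smaller than effective kernel size")
    Ho, Wo = (Hp - eh) // stride + 1, (Wp - ew) // stride + 1
    win = sliding_window_view(xp, (eh, ew), axis=(2, 3))
    win = win[:, :, ::stride, ::stride, ::dilation, ::dilation]  # (B,C,Ho,Wo,kh,kw)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(B * Ho * Wo, C * kh * kw)
    wmat = wd.reshape(O, C * kh * kw)
    out = (cols @ wmat.T).reshape(B, Ho, Wo, O).transpose(0, 3, 1, 2)
    _add_macs(B * Ho * Wo * O * C * kh * kw)
    if b is not None:
        out = out + b.data.reshape(1, O, 1, 1)

    def backward(g):
        g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(B * Ho * Wo, O)
        if w.requires_grad:
            w._accum((g2.T @ cols).reshape(O, C, kh, kw))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = (g2 @ wmat).reshape(B, Ho, Wo, C, kh, kw).transpose(0, 3, 4, 5, 1, 2)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i * dilation:i * dilation + Ho * stride:stride,
                        j * dilation:j * dilation + Wo * stride:stride] += dcols[:, :, i, j]
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accum(dxp)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, backward)


def maxpool2x2(x: Tensor) -> Tensor:
    B, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError(f"maxpool2x2 requires even spatial size, got {H}x{W}")
    v = x.data.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    v = v.reshape(B, C, H // 2, W // 2, 4)
    idx = v.argmax(axis=-1)
    out = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        gv = np.zeros((B, C, H // 2, W // 2, 4))
        np.put_along_axis(gv, idx[..., None], g[..., None], axis=-1)
        gx = gv.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H, W)
        x._accum(gx)

    return Tensor._make(out, (x,), backward)


def avgpool2x2(x: Tensor) -> Tensor:
    B, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError(f"avgpool2x2 requires even spatial size, got {H}x{W}")
    out = x.data.reshape(B, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))

    def backward(g):
        if x.requires_grad:
            gx = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) / 4.0
            x._accum(gx)

    return Tensor._make(out, (x,), backward)


def _resize_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic 1-D bilinear interpolation matrix (align_corners=False)."""
    M = np.zeros((n_out, n_in))
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    i0 = np.floor(src).astype(int)
    frac = src - i0
    lo = np.clip(i0, 0, n_in - 1)
    hi = np.clip(i0 + 1, 0, n_in - 1)
    np.add.at(M, (np.arange(n_out), lo), 1.0 - frac)
    np.add.at(M, (np.arange(n_out), hi), frac)
    return M


def resize_bilinear(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Bilinear resize of (B, C, H, W) to (B, C, *size), align_corners=False."""
    B, C, H, W = x.data.shape
    Ho, Wo = size
    Ry = _resize_matrix(Ho, H)
    Rx = _resize_matrix(Wo, W)
    out = np.einsum("oi,bcij,pj->bcop", Ry, x.data, Rx, optimize=True)

    def backward(g):
        if x.requires_grad:
            x._accum(np.einsum("oi,bcop,pj->bcij", Ry, g, Rx, optimize=True))

    return Tensor._make(out, (x,), backward)


def upsample2x(x: Tensor) -> Tensor:
    B, C, H, W = x.data.shape
    return resize_bilinear(x, (2 * H, 2 * W))


# ---------------------------------------------------------------------------
# Fourier transforms (full complex spectrum of a real map)
# ---------------------------------------------------------------------------


def fft2(x: Tensor) -> tuple[Tensor, Tensor]:
    """Full-spectrum 2-D DFT of a real (B, C, H, W) map -> (real, imag) parts."""
    spec = np.fft.fft2(x.data, axes=(-2, -1))
    H, W = x.data.shape[-2:]
    n = H * W

    re = Tensor(spec.real)
    im = Tensor(spec.imag)
    if x.requires_grad:
        def backward_re(g):
            x._accum(n * np.fft.ifft2(g, axes=(-2, -1)).real)

        def backward_im(g):
            x._accum(n * np.fft.ifft2(1j * g, axes=(-2, -1)).real)

        re.requires_grad = im.requires_grad = True
        re._parents = im._parents = (x,)
        re._backward = backward_re
        im._backward = backward_im
    return re, im


def ifft2(re: Tensor, im: Tensor) -> Tensor:
    """Real part of the inverse 2-D DFT of (real, imag) spectrum tensors."""
    if re.data.shape != im.data.shape:
        raise ValueError("real/imag spectra must share a shape")
    H, W = re.data.shape[-2:]
    n = H * W
    out = np.fft.ifft2(re.data + 1j * im.data, axes=(-2, -1)).real

    def backward(g):
        spec = np.fft.fft2(g, axes=(-2, -1))
        if re.requires_grad:
            re._accum(spec.real / n)
        if im.requires_grad:
            im._accum(spec.imag / n)

    return Tensor._make(out, (re, im), backward)


# ---------------------------------------------------------------------------
# Softmax
# ---------------------------------------------------------------------------


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if x.requires_grad:
            dot = (g * s).sum(axis=axis, keepdims=True)
            x._accum(s * (g - dot))

    return Tensor._make(s, (x,), backward)
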