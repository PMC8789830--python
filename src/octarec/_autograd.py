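"""Compact reverse-mode automatic differentiation on numpy arrays.

The engine provides exactly the tensor operations the reconstruction
networks and their composite perceptual loss need: broadcasting
elementwise arithmetic, reductions, 2-D convolution (via im2col),
parametric/leaky rectifiers, sigmoid, 2x2 average pooling, pixel
shuffle, channel concatenation and the magnitude of the 2-D discrete
Fourier transform.  Arrays default to float64 so that analytic
gradients can be checked against central differences to tight
tolerances; :func:`set_dtype` switches new tensors to float32 for
faster training (the :class:`working_dtype` context manager restores
the previous setting on exit).

Gradients are accumulated by a topological-order sweep over the
recorded operation graph (`Tensor.backward`).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "no_grad", "set_dtype", "get_dtype",
           "working_dtype"]

_EPS_FFT = 1e-12

_DTYPE = np.float64


def set_dtype(dtype) -> None:
    """Set the floating dtype newly created tensors are coerced to."""
    global _DTYPE
    dtype = np.dtype(dtype)
    if dtype not in (np.dtype(np.float32), np.dtype(np.float64)):
        raise ValueError("dtype must be float32 or float64")
    _DTYPE = dtype.type


def get_dtype():
    return _DTYPE


class working_dtype:
    """Context manager: use ``dtype`` for tensors created inside."""

    def __init__(self, dtype):
        self.dtype = dtype

    def __enter__(self):
        self._prev = get_dtype()
        set_dtype(self.dtype)
        return self

    def __exit__(self, *exc):
        set_dtype(self._prev)
        return False


class no_grad:
    """Context manager disabling graph recording (inference mode)."""

    _active = False

    def __enter__(self):
        self._prev = no_grad._active
        no_grad._active = True
        return self

    def __exit__(self, *exc):
        no_grad._active = self._prev
        return False


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
    return grad


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=_DTYPE))


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad) and not no_grad._active
        self._backward = None
        self._parents = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        parents = tuple(p for p in parents if isinstance(p, Tensor))
        if not no_grad._active and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, g):
        if not self.requires_grad:
            return
        g = _unbroadcast(g, self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)

        def bw(g):
            self._accum(g)
            other._accum(g)

        return Tensor._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __mul__(self, other):
        other = _as_tensor(other)

        def bw(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        return Tensor._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = _as_tensor(other)

        def bw(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / other.data**2)

        return Tensor._make(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, p: float):
        def bw(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(self.data**p, (self,), bw)

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(g):
            self._accum(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), bw)

    def abs(self):
        def bw(g):
            self._accum(g * np.sign(self.data))

        return Tensor._make(np.abs(self.data), (self,), bw)

    def clip(self, lo: float, hi: float):
        mask = (self.data >= lo) & (self.data <= hi)

        def bw(g):
            self._accum(g * mask)

        return Tensor._make(np.clip(self.data, lo, hi), (self,), bw)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self._accum(g * s * (1.0 - s))

        return Tensor._make(s, (self,), bw)

    # -- reductions / shape --------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        old = self.data.shape

        def bw(g):
            self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(*shape), (self,), bw)

    # -- activations ----------------------------------------------------------
    def prelu(self, alpha: "Tensor"):
        """Parametric ReLU with per-channel slope; input (N, C, H, W)."""
        a = alpha.data.reshape(1, -1, 1, 1)
        pos = self.data >= 0
        out_data = np.where(pos, self.data, a * self.data)

        def bw(g):
            self._accum(np.where(pos, g, a * g))
            alpha._accum(np.where(pos, 0.0, self.data * g).sum(axis=(0, 2, 3)))

        return Tensor._make(out_data, (self, alpha), bw)

    def leaky_relu(self, slope: float = 0.2):
        pos = self.data >= 0

        def bw(g):
            self._accum(np.where(pos, g, slope * g))

        return Tensor._make(np.where(pos, self.data, slope * self.data), (self,), bw)

    # -- structured ops -------------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor" = None, stride: int = 1,
               padding: int = 0):
        """2-D cross-correlation: input (N,C,H,W), weight (F,C,kh,kw).

        Large stride-1 kernels dispatch to an FFT product (same math,
        exact gradients via the correlation theorem); small or strided
        kernels use im2col.
        """
        x, w = self.data, weight.data
        n, c, h, wid = x.shape
        f, c2, kh, kw = w.shape
        if c != c2:
            raise ValueError(f"channel mismatch: input {c}, weight {c2}")
        s, p = int(stride), int(padding)
        if s == 1 and kh * kw >= 25:
            return self._conv2d_fft(weight, bias, p)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        oh = (xp.shape[2] - kh) // s + 1
        ow = (xp.shape[3] - kw) // s + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
        win = win[:, :, ::s, ::s]  # (N, C, OH, OW, kh, kw)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * kh * kw)
        wmat = w.reshape(f, c * kh * kw)
        out = cols @ wmat.T
        if bias is not None:
            out = out + bias.data
        out = out.reshape(n, oh, ow, f).transpose(0, 3, 1, 2)

        def bw(g):
            gm = g.transpose(0, 2, 3, 1).reshape(n * oh * ow, f)
            weight._accum((gm.T @ cols).reshape(w.shape))
            if bias is not None:
                bias._accum(gm.sum(axis=0))
            if self.requires_grad:
                dcols = (gm @ wmat).reshape(n, oh, ow, c, kh, kw)
                dxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, :, i:i + s * oh:s, j:j + s * ow:s] += \
                            dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                self._accum(dxp[:, :, p:p + h, p:p + wid] if p else dxp)

        parents = (self, weight) if bias is None else (self, weight, bias)
        return Tensor._make(out, parents, bw)

    def _conv2d_fft(self, weight: "Tensor", bias: "Tensor", p: int):
        """Stride-1 cross-correlation via real FFT products.

        With x zero-padded by p to size (Hp, Wp) and transforms taken at
        that size, out = irfft2(X * conj(W))[:OH, :OW]; the zero padding
        guarantees the circular correlation has no wrap-around inside
        the retained window.  Gradients reuse the same identity:
        dw = irfft2(sum_n X * conj(Dout))[:kh, :kw] and
        dx = irfft2(Dout * W) cropped back through the padding.
        """
        from scipy.fft import irfft2, next_fast_len, rfft2

        x, w = self.data, weight.data
        n, c, h, wid = x.shape
        f, _, kh, kw = w.shape
        oh, ow = h + 2 * p - kh + 1, wid + 2 * p - kw + 1
        sh = next_fast_len(h + 2 * p)
        sw = next_fast_len(wid + 2 * p)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        Xf = rfft2(xp, s=(sh, sw))
        Wf = rfft2(w, s=(sh, sw))
        out = irfft2(np.einsum("ncij,fcij->nfij", Xf, Wf.conj(),
                               optimize=True), s=(sh, sw))[:, :, :oh, :ow]
        if bias is not None:
            out = out + bias.data.reshape(1, f, 1, 1)
        out = np.ascontiguousarray(out)

        def bw(g):
            Df = rfft2(g, s=(sh, sw))
            weight._accum(irfft2(np.einsum("ncij,nfij->fcij", Xf, Df.conj(),
                                           optimize=True),
                                 s=(sh, sw))[:, :, :kh, :kw])
            if bias is not None:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if self.requires_grad:
                dxp = irfft2(np.einsum("nfij,fcij->ncij", Df, Wf,
                                       optimize=True), s=(sh, sw))
                self._accum(np.ascontiguousarray(
                    dxp[:, :, p:p + h, p:p + wid]))

        parents = (self, weight) if bias is None else (self, weight, bias)
        return Tensor._make(out, parents, bw)

    def avg_pool2(self):
        """2x2 average pooling, stride 2; odd trailing row/column dropped."""
        n, c, h, w = self.data.shape
        h2, w2 = h // 2, w // 2
        xc = self.data[:, :, :2 * h2, :2 * w2]
        out = xc.reshape(n, c, h2, 2, w2, 2).mean(axis=(3, 5))

        def bw(g):
            gx = np.zeros_like(self.data)
            gx[:, :, :2 * h2, :2 * w2] = np.repeat(
                np.repeat(g, 2, axis=2), 2, axis=3) / 4.0
            self._accum(gx)

        return Tensor._make(out, (self,), bw)

    def pixel_shuffle(self, s: int):
        """(N, C*s^2, H, W) -> (N, C, s*H, s*W), periodic rearrangement."""
        n, cs2, h, w = self.data.shape
        if cs2 % (s * s):
            raise ValueError(f"channels {cs2} not divisible by s^2={s * s}")
        c = cs2 // (s * s)
        out = (self.data.reshape(n, c, s, s, h, w)
               .transpose(0, 1, 4, 2, 5, 3).reshape(n, c, s * h, s * w))

        def bw(g):
            self._accum(g.reshape(n, c, h, s, w, s)
                        .transpose(0, 1, 3, 5, 2, 4).reshape(n, cs2, h, w))

        return Tensor._make(out, (self,), bw)

    def fft_mag2d(self):
        """Magnitude of the unnormalized 2-D DFT over the last two axes."""
        F = np.fft.fft2(self.data)
        mag = np.abs(F)

        def bw(g):
            ratio = F.conj() / np.maximum(mag, _EPS_FFT)
            self._accum(np.fft.fft2(g * ratio).real)

        return Tensor._make(mag, (self,), bw)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)

    def bw(g):
        start = 0
        for t, sz in zip(tensors, sizes):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(start, start + sz)
            t._accum(g[tuple(idx)])
            start += sz

    return Tensor._make(out, tensors, bw)
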