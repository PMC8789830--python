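"""Interpolation-based reconstruction baselines.

Upsampling uses separable interpolating kernels evaluated on the
sample-grid ("corner-pixel") convention matched to strided enface
downsampling: LR pixel (i, j) sits exactly at HR position (r*i, r*j),
so downsampling an upsampled image recovers the original samples
bit-for-bit.  Available kernels: nearest neighbour (block
replication), Keys bicubic (a = -0.5) and Lanczos with a = 3.  A
windowed bilateral filter — Gaussian in both space and intensity,
normalized over the valid window — serves as the classical quality
enhancement applied on top of bicubic upsampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BaselineConfig", "interpolate_upsample", "bilateral_filter",
           "METHODS"]

METHODS = ("nearest", "bicubic", "lanczos")


@dataclass(frozen=True)
class BaselineConfig:
    method: str = "bicubic"
    bilateral: bool = False
    bilateral_sigma_spatial: float = 3.0
    bilateral_sigma_range: float = 0.1

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.bilateral and (self.bilateral_sigma_spatial <= 0
                               or self.bilateral_sigma_range <= 0):
            raise ValueError("bilateral sigmas must be positive")


def _keys_cubic(t: np.ndarray) -> np.ndarray:
    """Keys cubic convolution kernel, a = -0.5 (Catmull-Rom)."""
    a = -0.5
    t = np.abs(t)
    out = np.zeros_like(t)
    near = t <= 1
    far = (t > 1) & (t < 2)
    out[near] = (a + 2) * t[near]**3 - (a + 3) * t[near]**2 + 1
    out[far] = a * t[far]**3 - 5 * a * t[far]**2 + 8 * a * t[far] - 4 * a
    return out


def _lanczos3(t: np.ndarray) -> np.ndarray:
    out = np.sinc(t) * np.sinc(t / 3.0)
    out[np.abs(t) >= 3] = 0.0
    return out


_KERNELS = {"bicubic": (_keys_cubic, 2), "lanczos": (_lanczos3, 3)}


def _interp_matrix(n_in: int, r: int, method: str) -> np.ndarray:
    """Row-stochastic (n_in*r, n_in) matrix mapping LR samples to HR axis."""
    n_out = n_in * r
    A = np.zeros((n_out, n_in))
    pos = np.arange(n_out) / r  # HR index X sits at LR coordinate X/r
    if method == "nearest":
        A[np.arange(n_out), (np.arange(n_out) // r)] = 1.0
        return A
    kernel, support = _KERNELS[method]
    for x, t in enumerate(pos):
        base = int(np.floor(t))
        ks = np.arange(base - support + 1, base + support + 1)
        w = kernel(t - ks)
        ks = np.clip(ks, 0, n_in - 1)  # clamp-to-edge
        for k, wk in zip(ks, w):
            A[x, k] += wk
        A[x] /= A[x].sum()
    return A


def interpolate_upsample(img, r: int, method: str = "bicubic") -> np.ndarray:
    """Upsample an enface image by ratio r with a separable kernel.

    Retained LR samples map back to their exact HR positions; output is
    clipped to [0, 1].
    """
    pixels = np.asarray(getattr(img, "pixels", img), dtype=np.float64)
    if pixels.ndim != 2:
        raise ValueError("expected a 2-D image")
    if r < 1:
        raise ValueError("ratio must be >= 1")
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if r == 1:
        return pixels.copy()
    A_rows = _interp_matrix(pixels.shape[0], r, method)
    A_cols = _interp_matrix(pixels.shape[1], r, method)
    return np.clip(A_rows @ pixels @ A_cols.T, 0.0, 1.0)


def bilateral_filter(img, sigma_spatial: float = 3.0,
                     sigma_range: float = 0.1) -> np.ndarray:
    """Edge-preserving smoothing with Gaussian spatial and range weights.

    Every output pixel is a convex combination of input pixels inside a
    window truncated at three spatial sigmas, with weights normalized
    over the in-bounds part of the window (no padding values enter).
    """
    pixels = np.asarray(getattr(img, "pixels", img), dtype=np.float64)
    if pixels.ndim != 2:
        raise ValueError("expected a 2-D image")
    if sigma_spatial <= 0 or sigma_range <= 0:
        raise ValueError("sigmas must be positive")
    radius = int(np.ceil(3.0 * sigma_spatial))
    h, w = pixels.shape
    acc = np.zeros_like(pixels)
    norm = np.zeros_like(pixels)
    inv2ss = 1.0 / (2.0 * sigma_spatial**2)
    inv2sr = 1.0 / (2.0 * sigma_range**2)
    for dy in range(-radius, radius + 1):
        ys = slice(max(dy, 0), min(h + dy, h))
        yd = slice(max(-dy, 0), min(h - dy, h))
        for dx in range(-radius, radius + 1):
            xs = slice(max(dx, 0), min(w + dx, w))
            xd = slice(max(-dx, 0), min(w - dx, w))
            shifted = pixels[ys, xs]
            center = pixels[yd, xd]
            wgt = np.exp(-(dy * dy + dx * dx) * inv2ss
                         - (shifted - center) ** 2 * inv2sr)
            acc[yd, xd] += wgt * shifted
            norm[yd, xd] += wgt
    return acc / norm
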