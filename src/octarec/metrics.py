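"""Evaluation suite: perceptual indices, angiogram-quality measures and
the acquisition-time model.

SSIM and PSNR wrap scikit-image with the conventions used throughout
the package (11x11 Gaussian window, sigma 1.5, data range 1).  MS-SSIM
is a plain-numpy multiscale implementation, independent of the
differentiable loss path, and doubles as its cross-check.  Vessel
connectivity binarizes an angiogram, thins it to a skeleton and
reports the fraction of skeleton pixels lying in components of at
least ``min_component`` pixels — disconnected specks lower the score.

The acquisition model converts an enface undersampling ratio r and a
repeat count into the implied scan-time speed-up: r-fold fewer scan
positions along each enface axis contributes r^2, and using n of the
base 8 repeats contributes 8/n, so (r=2, n=2) is 16x faster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.metrics import structural_similarity
from skimage.morphology import skeletonize

from .losses import WANG_WEIGHTS, gaussian_window, max_msssim_scales

__all__ = ["MetricsReport", "AcquisitionModel", "psnr", "ssim", "ms_ssim",
           "rms_contrast", "vessel_connectivity", "evaluate_pairs",
           "acquisition_speedup", "equivalent_step_size", "METRIC_NAMES"]

METRIC_NAMES = ("ssim", "ms_ssim", "psnr_db", "rms_contrast", "connectivity")

_CS_EPS = 1e-6


def _pixels(img) -> np.ndarray:
    return np.asarray(getattr(img, "pixels", img), dtype=np.float64)


def psnr(y, y_hat, data_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio, 10*log10(range^2 / MSE), in dB.

    Identical images have zero MSE; the result is flagged infinite with a
    warning and excluded from report means.
    """
    y, y_hat = _pixels(y), _pixels(y_hat)
    if y.shape != y_hat.shape:
        raise ValueError("shape mismatch")
    mse = float(np.mean((y - y_hat) ** 2))
    if mse == 0.0:
        warnings.warn("identical images: PSNR is infinite", RuntimeWarning)
        return np.inf
    return 10.0 * np.log10(data_range**2 / mse)


def ssim(y, y_hat, data_range: float = 1.0) -> float:
    """Single-scale SSIM, 11x11 Gaussian window, sigma 1.5."""
    y, y_hat = _pixels(y), _pixels(y_hat)
    if y.shape != y_hat.shape:
        raise ValueError("shape mismatch")
    if min(y.shape) < 11:
        raise ValueError("image smaller than the 11-pixel SSIM window")
    return float(structural_similarity(
        y, y_hat, win_size=11, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, data_range=data_range))


def _valid_conv(img: np.ndarray, win: np.ndarray) -> np.ndarray:
    return fftconvolve(img, win, mode="valid")


def ms_ssim(y, y_hat, scales: int = 5, window: int = 11,
            sigma: float = 1.5) -> float:
    """Multiscale SSIM with the standard per-scale exponents.

    Contrast-structure terms enter at every scale, luminance only at the
    coarsest; between scales the images are 2x2 average-pooled (odd
    trailing row/column dropped).  Exponents are renormalized when fewer
    than five scales are used.
    """
    y, y_hat = _pixels(y), _pixels(y_hat)
    if y.shape != y_hat.shape:
        raise ValueError("shape mismatch")
    feasible = max_msssim_scales(y.shape, window)
    if scales > feasible:
        raise ValueError(
            f"image {y.shape} supports at most {feasible} MS-SSIM scale(s) "
            f"with a {window}-pixel window; {scales} requested")
    weights = np.asarray(WANG_WEIGHTS[:scales], dtype=np.float64)
    weights = weights / weights.sum()
    win = gaussian_window(window, sigma)
    c1, c2 = 0.01**2, 0.03**2
    result = 1.0
    for j in range(scales):
        mu1, mu2 = _valid_conv(y, win), _valid_conv(y_hat, win)
        s11 = _valid_conv(y * y, win) - mu1**2
        s22 = _valid_conv(y_hat * y_hat, win) - mu2**2
        s12 = _valid_conv(y * y_hat, win) - mu1 * mu2
        cs = float(np.mean((2 * s12 + c2) / (s11 + s22 + c2)))
        if j < scales - 1:
            term = cs
        else:
            lum = float(np.mean((2 * mu1 * mu2 + c1) / (mu1**2 + mu2**2 + c1)))
            term = lum * cs
        result *= max(term, _CS_EPS) ** weights[j]
        if j < scales - 1:
            h2, w2 = y.shape[0] // 2, y.shape[1] // 2
            y = y[:2 * h2, :2 * w2].reshape(h2, 2, w2, 2).mean(axis=(1, 3))
            y_hat = y_hat[:2 * h2, :2 * w2].reshape(h2, 2, w2, 2).mean(axis=(1, 3))
    return float(result)


def rms_contrast(img) -> float:
    """Root-mean-square contrast: standard deviation of pixel intensities."""
    p = _pixels(img)
    if p.size == 0:
        raise ValueError("empty image")
    return float(p.std())


def vessel_connectivity(img, binarize="otsu", min_component: int = 5) -> float:
    """Fraction of skeleton pixels in components of >= ``min_component`` pixels.

    ``binarize`` is either "otsu" or an explicit threshold in [0, 1];
    foreground pixels are thinned to a one-pixel skeleton and components
    use 8-connectivity.  An empty foreground leaves the ratio undefined:
    NaN is returned with a warning so callers can exclude it.
    """
    p = _pixels(img)
    if binarize == "otsu":
        if np.all(p == p.flat[0]):
            thr = np.inf  # constant image: no foreground
        else:
            thr = threshold_otsu(p)
    else:
        thr = float(binarize)
    fg = p > thr
    if not fg.any():
        warnings.warn("empty foreground: connectivity undefined", RuntimeWarning)
        return np.nan
    skel = skeletonize(fg)
    total = int(skel.sum())
    if total == 0:
        warnings.warn("empty skeleton: connectivity undefined", RuntimeWarning)
        return np.nan
    labels = label(skel, connectivity=2)
    sizes = np.bincount(labels.ravel())[1:]
    connected = int(sizes[sizes >= min_component].sum())
    return connected / total


@dataclass
class MetricsReport:
    """Per-image metric table and per-method mean/std summary."""

    per_image: pd.DataFrame
    summary: pd.DataFrame

    def to_csv(self, per_image_path, summary_path=None) -> None:
        self.per_image.to_csv(per_image_path, index=False)
        if summary_path is not None:
            self.summary.to_csv(summary_path)

    def to_json(self) -> str:
        return self.summary.to_json(orient="index")


def evaluate_pairs(pairs, methods: dict, ms_ssim_scales=None,
                   connectivity_binarize="otsu",
                   connectivity_min_component: int = 5) -> MetricsReport:
    """Score reconstruction methods against the (HR, HQ) ground truth.

    ``methods`` maps a method name to a callable taking the (LR, LQ)
    pixels and returning the HR reconstruction.  Non-finite PSNR and
    undefined connectivity values are excluded from the summary.
    """
    if ms_ssim_scales is None:
        hr_shape = pairs[0].hr_hq.shape
        ms_ssim_scales = min(5, max_msssim_scales(hr_shape))
    rows = []
    for idx, pair in enumerate(pairs):
        gt = pair.hr_hq.pixels
        for name, fn in methods.items():
            rec = np.asarray(fn(pair.lr_lq.pixels), dtype=np.float64)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                rows.append({
                    "image": idx, "method": name,
                    "ssim": ssim(gt, rec),
                    "ms_ssim": ms_ssim(gt, rec, scales=ms_ssim_scales),
                    "psnr_db": psnr(gt, rec),
                    "rms_contrast": rms_contrast(rec),
                    "connectivity": vessel_connectivity(
                        rec, binarize=connectivity_binarize,
                        min_component=connectivity_min_component),
                })
    per_image = pd.DataFrame(rows)
    finite = per_image.replace([np.inf, -np.inf], np.nan)
    grouped = finite.groupby("method")[list(METRIC_NAMES)]
    summary = pd.concat({"mean": grouped.mean(), "std": grouped.std()}, axis=1)
    return MetricsReport(per_image=per_image, summary=summary)


@dataclass(frozen=True)
class AcquisitionModel:
    """Timing model of the fully-sampled 8-repeat acquisition protocol."""

    base_step_um: float = 10.0
    base_repeats: int = 8
    base_time_s: float = 17.8
    enface_points: tuple = (400, 400)

    def __post_init__(self):
        if min(self.base_step_um, self.base_repeats, self.base_time_s,
               *self.enface_points) <= 0:
            raise ValueError("all acquisition-model fields must be positive")


def _round_time(x: float) -> float:
    """Two significant figures, but never coarser than 0.1 s (so the base
    17.8 s protocol time is reported as printed)."""
    if x == 0:
        return 0.0
    decimals = max(1, 1 - int(np.floor(np.log10(abs(x)))))
    return float(round(x, decimals))


def acquisition_speedup(model: AcquisitionModel, r: int, n_repeats: int):
    """(speed-up factor, acquisition time in s, 2 significant figures).

    Undersampling both enface axes by r gives r^2 fewer scan positions;
    using n of the base repeats gives a further base_repeats/n factor.
    """
    if r < 1:
        raise ValueError("ratio must be >= 1")
    if not (1 <= n_repeats <= model.base_repeats):
        raise ValueError(f"n_repeats must be in 1..{model.base_repeats}")
    speedup = r * r * model.base_repeats / n_repeats
    return speedup, _round_time(model.base_time_s / speedup)


def equivalent_step_size(model: AcquisitionModel, r: int) -> float:
    """Scanning step size (micrometers) equivalent to undersampling by r."""
    if r < 1:
        raise ValueError("ratio must be >= 1")
    return model.base_step_um * r
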