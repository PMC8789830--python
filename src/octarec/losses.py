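"""Differentiable training objectives for angiogram reconstruction.

The reconstruction loss combines three terms on [0, 1]-normalized
enface angiograms Y (ground truth) and Y_hat (reconstruction):

* MAE        -- (1/N) sum |Y - Y_hat|, the primary term;
* MS-SSIM    -- 1 - MSSSIM(Y, Y_hat), preserving local structure and
                contrast across dyadic scales;
* Fourier MAE -- (1/N) sum ||F(Y)| - |F(Y_hat)||, the mean absolute
                difference of unnormalized 2-D DFT magnitudes, which
                penalizes the periodic frequency-space remnants of
                enface undersampling.

The combined loss is  MAE + 0.8 * MS-SSIM-loss + 7e-5 * FMAE.  For
adversarial training the generator adds 5e-3 * (-log D(G(X))) and the
discriminator minimizes -[log D(Y) + log(1 - D(G(X)))].

All functions accept 2-D images or (batch, H, W) stacks as numpy
arrays, EnfaceImage objects or autodiff tensors, and return a scalar
autodiff tensor (use ``.item()`` for the float value).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autograd import Tensor

__all__ = ["LossConfig", "mae_loss", "msssim_loss", "fmae_loss",
           "combined_loss", "generator_adv_loss", "discriminator_loss",
           "max_msssim_scales", "WANG_WEIGHTS"]

#: per-scale exponents of the standard five-scale MS-SSIM
WANG_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)

_LOG_EPS = 1e-8
_CS_EPS = 1e-6


@dataclass(frozen=True)
class LossConfig:
    """Loss-term weights and MS-SSIM settings."""

    w_msssim: float = 0.8
    w_fmae: float = 7e-5
    w_adv: float = 5e-3
    msssim_scales: int = 5
    msssim_window: int = 11
    msssim_sigma: float = 1.5

    def __post_init__(self):
        if min(self.w_msssim, self.w_fmae, self.w_adv) < 0:
            raise ValueError("loss weights must be >= 0")
        if self.msssim_scales < 1:
            raise ValueError("msssim_scales must be >= 1")
        if self.msssim_window % 2 == 0:
            raise ValueError("msssim_window must be odd")


def _as_batch(img) -> Tensor:
    """Coerce to a (N, 1, H, W) tensor, sharing the graph when given one."""
    if not isinstance(img, Tensor):
        img = Tensor(np.asarray(getattr(img, "pixels", img), dtype=np.float64))
    if img.ndim == 2:
        return img.reshape(1, 1, *img.shape)
    if img.ndim == 3:
        return img.reshape(img.shape[0], 1, img.shape[1], img.shape[2])
    if img.ndim == 4:
        return img
    raise ValueError("expected 2-D image(s)")


def _check_shapes(y: Tensor, y_hat: Tensor):
    if y.shape != y_hat.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {y_hat.shape}")


def mae_loss(y, y_hat) -> Tensor:
    """Mean absolute error (1/N) sum |Y - Y_hat|."""
    y, y_hat = _as_batch(y), _as_batch(y_hat)
    _check_shapes(y, y_hat)
    return (y - y_hat).abs().mean()


def gaussian_window(size: int, sigma: float) -> np.ndarray:
    """Normalized 2-D Gaussian window used by SSIM/MS-SSIM."""
    half = (size - 1) / 2.0
    x = np.arange(size) - half
    g = np.exp(-(x**2) / (2.0 * sigma**2))
    w = np.outer(g, g)
    return w / w.sum()


def max_msssim_scales(shape, window: int = 11) -> int:
    """Largest dyadic scale count the image size supports."""
    m = min(shape[-2], shape[-1])
    scales = 0
    while m >= window:
        scales += 1
        m //= 2
    return scales


def _ssim_terms(y: Tensor, y_hat: Tensor, win: Tensor):
    """Mean luminance and contrast-structure terms over the valid region."""
    c1, c2 = 0.01**2, 0.03**2
    mu1 = y.conv2d(win)
    mu2 = y_hat.conv2d(win)
    s11 = (y * y).conv2d(win) - mu1 * mu1
    s22 = (y_hat * y_hat).conv2d(win) - mu2 * mu2
    s12 = (y * y_hat).conv2d(win) - mu1 * mu2
    lum = ((mu1 * mu2 * 2.0 + c1) / (mu1 * mu1 + mu2 * mu2 + c1)).mean()
    cs = ((s12 * 2.0 + c2) / (s11 + s22 + c2)).mean()
    return lum, cs


def _msssim(y: Tensor, y_hat: Tensor, cfg: LossConfig) -> Tensor:
    scales = cfg.msssim_scales
    feasible = max_msssim_scales(y.shape, cfg.msssim_window)
    if scales > feasible:
        raise ValueError(
            f"image {y.shape[-2:]} supports at most {feasible} MS-SSIM "
            f"scale(s) with a {cfg.msssim_window}-pixel window; "
            f"{scales} requested")
    weights = np.asarray(WANG_WEIGHTS[:scales], dtype=np.float64)
    weights = weights / weights.sum()
    win = Tensor(gaussian_window(cfg.msssim_window, cfg.msssim_sigma)
                 .reshape(1, 1, cfg.msssim_window, cfg.msssim_window))
    result = None
    for j in range(scales):
        lum, cs = _ssim_terms(y, y_hat, win)
        term = cs if j < scales - 1 else lum * cs
        factor = term.clip(_CS_EPS, np.inf) ** float(weights[j])
        result = factor if result is None else result * factor
        if j < scales - 1:
            y, y_hat = y.avg_pool2(), y_hat.avg_pool2()
    return result


def msssim_loss(y, y_hat, cfg: LossConfig = LossConfig()) -> Tensor:
    """1 - MSSSIM(Y, Y_hat); 0 for identical images, symmetric."""
    y, y_hat = _as_batch(y), _as_batch(y_hat)
    _check_shapes(y, y_hat)
    return 1.0 - _msssim(y, y_hat, cfg)


def fmae_loss(y, y_hat) -> Tensor:
    """MAE between unnormalized 2-D DFT magnitudes, divided by N once."""
    y, y_hat = _as_batch(y), _as_batch(y_hat)
    _check_shapes(y, y_hat)
    return (y.fft_mag2d() - y_hat.fft_mag2d()).abs().mean()


def combined_loss(y, y_hat, cfg: LossConfig = LossConfig()) -> Tensor:
    """MAE + w_msssim * MS-SSIM-loss + w_fmae * FMAE."""
    return (mae_loss(y, y_hat)
            + cfg.w_msssim * msssim_loss(y, y_hat, cfg)
            + cfg.w_fmae * fmae_loss(y, y_hat))


def _check_prob(p, name: str):
    vals = p.data if isinstance(p, Tensor) else np.asarray(p, dtype=np.float64)
    if np.any(vals <= 0.0) or np.any(vals >= 1.0):
        raise ValueError(f"{name} must lie strictly in (0, 1)")
    return p if isinstance(p, Tensor) else Tensor(vals)


def generator_adv_loss(y, y_hat, d_out, cfg: LossConfig = LossConfig()) -> Tensor:
    """Adversarial generator objective: combined loss + w_adv * (-log D(G(X)))."""
    d_out = _check_prob(d_out, "d_out")
    neg_log = -((d_out + _LOG_EPS).log().mean())
    return combined_loss(y, y_hat, cfg) + cfg.w_adv * neg_log


def discriminator_loss(d_real, d_fake) -> Tensor:
    """-[log D(real) + log(1 - D(fake))], the negated inner GAN objective."""
    d_real = _check_prob(d_real, "d_real")
    d_fake = _check_prob(d_fake, "d_fake")
    return -(((d_real + _LOG_EPS).log().mean())
             + ((1.0 - d_fake + _LOG_EPS).log().mean()))
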