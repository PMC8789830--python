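"""Angiogram formation and training-pair construction.

A decorrelation angiogram is computed from ``n_use`` repeated frames as
the mean absolute difference over adjacent frame pairs, min-max
normalized to [0, 1] per volume: a first-order decorrelation estimator
whose variance shrinks as more repeats are averaged, so an 8-repeat
angiogram is cleaner than a 2-repeat one.

Supervised records pair three views of the same scene:

* ``hr_hq`` — 8-repeat angiogram of the fully-sampled series (target),
* ``hr_lq`` — 2-repeat angiogram from a randomly chosen adjacent repeat
  pair of the same series,
* ``lr_lq`` — the same 2-repeat angiogram computed on the series after
  strided enface downsampling by ratio ``r`` (the network input).

Strided subsampling (keep every r-th sample in x and y) mimics a raster
scan with an r-times larger step: a coarser scan skips positions, it
does not average them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .phantom import VolumeSeries

__all__ = ["AngiogramVolume", "EnfaceImage", "PairedSample",
           "compute_angiogram", "downsample_enface", "make_pairs", "mip",
           "section_and_filter", "split_dataset", "augment",
           "dihedral_transform", "dihedral_inverse", "N_DIHEDRAL"]

#: order of the symmetry group of the square (rotations x flips)
N_DIHEDRAL = 8


@dataclass
class AngiogramVolume:
    """One decorrelation volume, values (X, Y, Z) in [0, 1]."""

    values: np.ndarray
    n_repeats_used: int
    sampling_ratio: int = 1

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("values must be (X, Y, Z)")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("values must lie in [0, 1]")
        if self.n_repeats_used < 2:
            raise ValueError("n_repeats_used must be >= 2")

    @property
    def shape(self):
        return self.values.shape


@dataclass
class EnfaceImage:
    """A 2-D enface angiogram: one depth slice or a depth MIP."""

    pixels: np.ndarray
    kind: str = "sectioned"
    depth_index: Optional[int] = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be 2-D")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("pixels must lie in [0, 1]")
        if self.kind not in ("sectioned", "mip"):
            raise ValueError("kind must be 'sectioned' or 'mip'")
        if self.kind == "mip":
            self.depth_index = None

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class PairedSample:
    """Aligned (LR,LQ) input, (HR,LQ) intermediate and (HR,HQ) target."""

    lr_lq: EnfaceImage
    hr_lq: EnfaceImage
    hr_hq: EnfaceImage
    ratio: int

    def __post_init__(self):
        if self.hr_lq.shape != self.hr_hq.shape:
            raise ValueError("hr_lq and hr_hq must share a shape")
        hx, hy = self.hr_hq.shape
        if (hx % self.ratio) or (hy % self.ratio):
            raise ValueError("HR shape not divisible by ratio")
        if self.lr_lq.shape != (hx // self.ratio, hy // self.ratio):
            raise ValueError("lr_lq shape must equal HR shape / ratio")


def compute_angiogram(series: VolumeSeries, first_repeat: int = 0,
                      n_use: Optional[int] = None,
                      normalize: bool = True) -> AngiogramVolume:
    """Decorrelation angiogram from ``n_use`` frames starting at ``first_repeat``.

    value(x,y,z) = mean over adjacent frame pairs of |frame_{i+1} - frame_i|,
    then min-max normalized per volume.  A zero-range (all-constant)
    pre-normalization volume maps to all zeros.  ``normalize=False`` returns
    the raw estimate, useful for dispersion studies across repeat counts.
    """
    R = series.n_repeats
    if n_use is None:
        n_use = R - first_repeat
    if n_use < 2:
        raise ValueError("n_use must be >= 2: an angiogram needs inter-frame signal")
    if first_repeat < 0 or first_repeat + n_use > R:
        raise ValueError(f"repeats [{first_repeat}, {first_repeat + n_use}) "
                         f"outside series of {R} repeats")
    frames = series.frames[first_repeat:first_repeat + n_use]
    est = np.abs(np.diff(frames, axis=0)).mean(axis=0)
    if normalize:
        lo, hi = est.min(), est.max()
        est = np.zeros_like(est) if hi - lo == 0 else (est - lo) / (hi - lo)
    else:
        est = np.clip(est, 0.0, 1.0)
    return AngiogramVolume(values=est, n_repeats_used=n_use,
                           sampling_ratio=series.sampling_ratio)


def downsample_enface(vol: Union[AngiogramVolume, VolumeSeries],
                      r: int) -> Union[AngiogramVolume, VolumeSeries]:
    """Strided enface subsampling by ratio ``r`` (depth untouched)."""
    if r < 1:
        raise ValueError("ratio must be >= 1")
    if isinstance(vol, VolumeSeries):
        _, x, y, _ = vol.frames.shape
        if x % r or y % r:
            raise ValueError(f"enface shape ({x}, {y}) not divisible by {r}")
        return VolumeSeries(frames=vol.frames[:, ::r, ::r, :],
                            vessel_mask=vol.vessel_mask[::r, ::r, :],
                            spec=vol.spec,
                            sampling_ratio=vol.sampling_ratio * r)
    x, y, _ = vol.values.shape
    if x % r or y % r:
        raise ValueError(f"enface shape ({x}, {y}) not divisible by {r}")
    return AngiogramVolume(values=vol.values[::r, ::r, :],
                           n_repeats_used=vol.n_repeats_used,
                           sampling_ratio=vol.sampling_ratio * r)


def make_pairs(series: VolumeSeries, r: int, seed: int,
               min_vessel_fraction: float = 0.0,
               threshold: float = 0.1) -> list[PairedSample]:
    """Build one PairedSample per retained depth slice of a full series.

    The target is the 8-repeat angiogram of the full series; a uniformly
    random adjacent repeat pair (i, i+1) supplies both the (HR,LQ)
    angiogram and — after enface downsampling by ``r`` — the (LR,LQ)
    input.  Depth slices are retained when the target slice's fraction of
    pixels above ``threshold`` reaches ``min_vessel_fraction``.
    """
    R = series.n_repeats
    if R < 8:
        raise ValueError("pair construction needs a series of >= 8 repeats")
    rng = np.random.default_rng(seed)
    i = int(rng.integers(0, R - 1))  # adjacent pair (i, i+1)
    hr_hq = compute_angiogram(series, 0, 8)
    hr_lq = compute_angiogram(series, i, 2)
    lr_lq = compute_angiogram(downsample_enface(series, r), i, 2)
    pairs = []
    for z in range(hr_hq.values.shape[2]):
        target = hr_hq.values[:, :, z]
        if np.mean(target > threshold) < min_vessel_fraction:
            continue
        pairs.append(PairedSample(
            lr_lq=EnfaceImage(lr_lq.values[:, :, z], "sectioned", z),
            hr_lq=EnfaceImage(hr_lq.values[:, :, z], "sectioned", z),
            hr_hq=EnfaceImage(target, "sectioned", z),
            ratio=r))
    return pairs


def mip(vol: AngiogramVolume, depth_range: Optional[tuple] = None) -> EnfaceImage:
    """Maximum intensity projection over a half-open depth range [z0, z1)."""
    z = vol.values.shape[2]
    z0, z1 = (0, z) if depth_range is None else depth_range
    if not (0 <= z0 < z1 <= z):
        raise ValueError(f"empty or out-of-bounds depth range ({z0}, {z1})")
    return EnfaceImage(vol.values[:, :, z0:z1].max(axis=2), kind="mip")


def section_and_filter(vol: AngiogramVolume, min_vessel_fraction: float = 0.02,
                       threshold: float = 0.1) -> list[EnfaceImage]:
    """Depth slices with sufficient vessel content.

    A slice is kept when its fraction of pixels above ``threshold`` is at
    least ``min_vessel_fraction`` — an automated proxy for manual selection
    of slices with sufficient vessel profiles.
    """
    if not (0.0 <= min_vessel_fraction <= 1.0):
        raise ValueError("min_vessel_fraction must be in [0, 1]")
    kept = []
    for z in range(vol.values.shape[2]):
        sl = vol.values[:, :, z]
        if np.mean(sl > threshold) >= min_vessel_fraction:
            kept.append(EnfaceImage(sl, "sectioned", z))
    return kept


def split_dataset(n: int, ratio: tuple = (9, 1), seed: int = 0):
    """Random disjoint, exhaustive train/validation index split.

    The train share is ``round(n * ratio[0] / sum(ratio))``; for the
    protocol ratio 9:1 and n=2000 this yields 1800/200.
    """
    if n < 2:
        raise ValueError("need at least two samples to split")
    if ratio[0] <= 0 or ratio[1] <= 0:
        raise ValueError("ratio components must be positive")
    n_train = int(round(n * ratio[0] / (ratio[0] + ratio[1])))
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    return perm[:n_train].copy(), perm[n_train:].copy()


def dihedral_transform(pixels: np.ndarray, element: int) -> np.ndarray:
    """Apply element ``k + 4*flip`` of the square's symmetry group.

    Elements 0-3 are counter-clockwise rotations by 90 deg * k; elements
    4-7 additionally flip along the second axis after rotating.
    """
    if not (0 <= element < N_DIHEDRAL):
        raise ValueError("element must be in 0..7")
    if pixels.shape[0] != pixels.shape[1]:
        raise ValueError("dihedral transforms require a square image")
    out = np.rot90(pixels, k=element % 4)
    if element >= 4:
        out = out[:, ::-1]
    return np.ascontiguousarray(out)


def dihedral_inverse(element: int) -> int:
    """Index of the inverse group element."""
    if element < 4:
        return (4 - element) % 4
    return element  # rot-then-flip elements are involutions


def augment(img: Union[EnfaceImage, "PairedSample"], seed: int):
    """Random rotation/flip augmentation (one of the 8 square symmetries).

    Applied to a PairedSample, the same element transforms all three
    images so the pair stays aligned.
    """
    element = int(np.random.default_rng(seed).integers(0, N_DIHEDRAL))
    if isinstance(img, PairedSample):
        def tx(e: EnfaceImage) -> EnfaceImage:
            return EnfaceImage(dihedral_transform(e.pixels, element),
                               e.kind, e.depth_index)
        return PairedSample(tx(img.lr_lq), tx(img.hr_lq), tx(img.hr_hq),
                            img.ratio)
    return EnfaceImage(dihedral_transform(img.pixels, element),
                       img.kind, img.depth_index)
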