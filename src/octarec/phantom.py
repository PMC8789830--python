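"""Synthetic vascular phantoms with repeat-to-repeat flow decorrelation.

OCT angiography contrasts moving blood against static tissue by
comparing repeated B-scans acquired at the same location: voxels inside
perfused vessels decorrelate from repeat to repeat, static tissue does
not.  This module builds volumes with that statistical structure —
random-walk vessel tubes embedded in a smoothed speckle background —
and simulates a stack of repeated acquisition frames in which the
vessel signal follows a stationary AR(1) process whose one-repeat
correlation is ``1 - flow_decorrelation`` while static voxels vary only
by additive noise.

The geometry is deliberately schematic (connected curvilinear tubes,
not anatomy): it provides exactly the features the downstream stages
need — decorrelating flow voxels, a static background, and connected
vessel skeletons for the connectivity metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["PhantomSpec", "VolumeSeries", "generate_vessel_volume",
           "simulate_repeats", "make_series"]

# Static baseline intensity inside vessels and stationary flow amplitude.
# Vessels in real decorrelation angiograms are bright against tissue; the
# amplitude sets how strongly the flow term perturbs that baseline.
VESSEL_LEVEL = 0.55
FLOW_SIGMA = 0.15


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic vascular volume.

    grid_size       -- (X, Y, Z) voxel counts, each >= 8
    n_vessels       -- number of random-walk vessel tubes
    radius_range    -- (min, max) tube radius in voxels
    flow_decorrelation -- per-repeat correlation loss inside vessels, in [0, 1];
                       0 means flow is frozen across repeats, 1 means each
                       repeat resamples the flow signal independently
    static_noise_sigma -- additive Gaussian noise applied to every voxel of
                       every repeat (the acquisition-noise floor)
    seed            -- integer seed; identical specs produce identical volumes
    """

    grid_size: tuple = (64, 64, 64)
    n_vessels: int = 6
    radius_range: tuple = (1.5, 3.0)
    flow_decorrelation: float = 0.7
    static_noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if len(self.grid_size) != 3 or any(int(g) < 8 for g in self.grid_size):
            raise ValueError("grid_size must be three components, each >= 8")
        if self.n_vessels < 0:
            raise ValueError("n_vessels must be >= 0")
        lo, hi = self.radius_range
        if not (0 < lo <= hi):
            raise ValueError("radius_range must satisfy 0 < min <= max")
        if not (0.0 <= self.flow_decorrelation <= 1.0):
            raise ValueError("flow_decorrelation must be in [0, 1]")
        if self.static_noise_sigma < 0:
            raise ValueError("static_noise_sigma must be >= 0")
        if 2 * lo + 1 > min(self.grid_size):
            raise ValueError(
                f"grid {self.grid_size} too small to contain a vessel of "
                f"radius {lo}")


@dataclass
class VolumeSeries:
    """Repeated acquisition frames plus the ground-truth flow map.

    frames has shape (R, X, Y, Z) with intensities in [0, 1]; vessel_mask
    is boolean (X, Y, Z).  sampling_ratio records cumulative enface
    downsampling applied to the series (1 for a fully-sampled volume).
    """

    frames: np.ndarray
    vessel_mask: np.ndarray
    spec: PhantomSpec
    sampling_ratio: int = 1

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float64)
        self.vessel_mask = np.asarray(self.vessel_mask, dtype=bool)
        if self.frames.ndim != 4 or self.frames.shape[0] < 2:
            raise ValueError("frames must be (R>=2, X, Y, Z)")
        if self.vessel_mask.shape != self.frames.shape[1:]:
            raise ValueError("vessel_mask shape must match frames' spatial shape")
        if self.frames.min() < 0 or self.frames.max() > 1:
            raise ValueError("frame intensities must lie in [0, 1]")

    @property
    def n_repeats(self) -> int:
        return self.frames.shape[0]


def _random_walk_centerline(rng: np.random.Generator, grid, persistence=0.85):
    """Correlated random walk through the grid; returns integer voxel path."""
    grid = np.asarray(grid, dtype=float)
    pos = rng.uniform(0.15, 0.85, 3) * grid
    d = rng.normal(size=3)
    d /= np.linalg.norm(d)
    n_steps = int(2.0 * grid.max())
    pts = []
    for _ in range(n_steps):
        pts.append(pos.copy())
        d = persistence * d + (1 - persistence) * rng.normal(size=3)
        d /= max(np.linalg.norm(d), 1e-9)
        pos = pos + d
        if np.any(pos < 0) or np.any(pos >= grid):
            break
    idx = np.round(np.array(pts)).astype(int)
    idx = idx[np.all((idx >= 0) & (idx < grid.astype(int)), axis=1)]
    return idx


def generate_vessel_volume(spec: PhantomSpec):
    """Build (vessel_mask, tissue_volume) for a phantom specification.

    The mask is the union of ``n_vessels`` random-walk tubes with per-vessel
    radii drawn from ``radius_range``; the tissue volume is a smoothed,
    clipped Gaussian speckle background in [0, 1].  Deterministic in
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(g) for g in spec.grid_size)
    mask = np.zeros(shape, dtype=bool)
    for _ in range(spec.n_vessels):
        radius = rng.uniform(*spec.radius_range)
        center = _random_walk_centerline(rng, shape)
        if len(center) == 0:
            continue
        line = np.zeros(shape, dtype=bool)
        line[center[:, 0], center[:, 1], center[:, 2]] = True
        dist = ndimage.distance_transform_edt(~line)
        mask |= dist <= radius
    speckle = ndimage.gaussian_filter(rng.normal(size=shape), sigma=1.0)
    sd = speckle.std()
    if sd > 0:
        speckle /= sd
    tissue = np.clip(0.30 + 0.08 * speckle, 0.0, 1.0)
    return mask, tissue


def simulate_repeats(vessel_mask: np.ndarray, tissue_volume: np.ndarray,
                     n_repeats: int, spec: PhantomSpec) -> VolumeSeries:
    """Simulate repeated frames over a phantom.

    Static voxels carry the tissue intensity plus i.i.d. additive noise of
    scale ``static_noise_sigma`` per repeat.  Vessel voxels replace the
    tissue value by a bright baseline plus a stationary AR(1) flow term with
    one-repeat correlation ``rho = 1 - flow_decorrelation`` and stationary
    standard deviation ``FLOW_SIGMA``.  Frames are clipped to [0, 1].
    """
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    tissue_volume = np.asarray(tissue_volume, dtype=np.float64)
    if vessel_mask.shape != tissue_volume.shape:
        raise ValueError("vessel_mask and tissue_volume shapes differ")
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    rng = np.random.default_rng([spec.seed, 0x5E])
    rho = 1.0 - spec.flow_decorrelation
    n_flow = int(vessel_mask.sum())
    base = tissue_volume.copy()
    base[vessel_mask] = VESSEL_LEVEL
    frames = np.empty((n_repeats,) + tissue_volume.shape)
    flow = rng.normal(0.0, FLOW_SIGMA, n_flow)
    innov_sd = FLOW_SIGMA * np.sqrt(max(0.0, 1.0 - rho * rho))
    for t in range(n_repeats):
        if t > 0:
            flow = rho * flow + innov_sd * rng.normal(size=n_flow)
        frame = base.copy()
        frame[vessel_mask] += flow
        if spec.static_noise_sigma > 0:
            frame = frame + rng.normal(0.0, spec.static_noise_sigma,
                                       tissue_volume.shape)
        frames[t] = np.clip(frame, 0.0, 1.0)
    return VolumeSeries(frames=frames, vessel_mask=vessel_mask, spec=spec)


def make_series(spec: PhantomSpec, n_repeats: int = 8) -> VolumeSeries:
    """Convenience: generate a phantom and simulate its repeat series."""
    mask, tissue = generate_vessel_volume(spec)
    return simulate_repeats(mask, tissue, n_repeats, spec)
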