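"""Histogram and gray-level preprocessing.

Two preprocessing chains feed the texture features:

* first-order (histogram) features use the original-resolution in-mask
  voxels, binned with a data-driven bin count — the median of the Sturges,
  Scott and Freedman-Diaconis rules;
* second-order (co-occurrence) features use an isotropically resampled
  grid quantized to a fixed number of gray levels (200 by default), so that
  all 13 neighbor offsets span comparable physical distances and the
  co-occurrence matrix is not too sparse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import distance_transform_edt, map_coordinates

from .exceptions import DomainError, EmptyRoiError
from .volume_io import RoiMask, VolumeGrid, _check_aligned

__all__ = [
    "TextureConfig",
    "Histogram",
    "QuantizedRoi",
    "bins_sturges",
    "bins_scott",
    "bins_freedman_diaconis",
    "select_bin_count",
    "build_histogram",
    "resample_isotropic",
    "quantize",
]


@dataclass(frozen=True)
class TextureConfig:
    """Tunable preprocessing/feature knobs with their study defaults.

    ng_levels : int
        Gray levels for quantization (default 200).
    isotropic_mm : float or None
        Target isotropic voxel edge; ``None`` means the minimum input
        spacing (min-edge rule).
    histogram_rule : str
        'median3' (median of Sturges/Scott/Freedman-Diaconis), or one of
        'sturges', 'scott', 'fd'.
    intensity_bounds : str or tuple
        'roi' quantizes between the in-mask extrema; a (lo, hi) tuple uses
        fixed bounds (e.g. (0, 100) for the full PDFF scale).
    entropy_log_base : float
        Base of the co-occurrence entropy logarithm (2 -> bits).
    """

    ng_levels: int = 200
    isotropic_mm: float | None = None
    histogram_rule: str = "median3"
    intensity_bounds: str | tuple[float, float] = "roi"
    entropy_log_base: float = 2.0


@dataclass(frozen=True)
class Histogram:
    """A normalized intensity histogram (probabilities sum to 1)."""

    bin_edges: np.ndarray     # k+1 increasing values
    bin_centers: np.ndarray   # k values
    probabilities: np.ndarray # k values, >= 0, sum 1

    @property
    def k(self) -> int:
        return len(self.probabilities)


@dataclass
class QuantizedRoi:
    """Gray-level quantized ROI: integer levels 1..ng inside the mask, 0 outside."""

    levels: np.ndarray
    ng: int
    mask: RoiMask
    spacing: tuple[float, float, float]


def bins_sturges(n: int) -> int:
    """Sturges' rule: ceil(log2 n) + 1 bins for a sample of size n."""
    if n < 1:
        raise DomainError(f"sample size must be >= 1, got {n}")
    return int(math.ceil(math.log2(n))) + 1


def bins_scott(values) -> int:
    """Scott's rule: bin width 3.49 * s * n^(-1/3), s the sample SD (ddof=1)."""
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 2:
        raise DomainError("Scott's rule needs at least 2 values")
    s = float(np.std(v, ddof=1))
    rng = float(v.max() - v.min())
    if s == 0.0 or rng == 0.0:
        return 1
    h = 3.49 * s * n ** (-1.0 / 3.0)
    return max(1, int(math.ceil(rng / h)))


def bins_freedman_diaconis(values) -> int:
    """Freedman-Diaconis rule: width 2*IQR*n^(-1/3); zero IQR falls back to Sturges.

    Quartiles use linear interpolation between order statistics.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 2:
        raise DomainError("Freedman-Diaconis rule needs at least 2 values")
    rng = float(v.max() - v.min())
    if rng == 0.0:
        return 1
    q25, q75 = np.percentile(v, [25.0, 75.0])
    iqr = float(q75 - q25)
    if iqr == 0.0:
        return bins_sturges(n)
    h = 2.0 * iqr * n ** (-1.0 / 3.0)
    return max(1, int(math.ceil(rng / h)))


def select_bin_count(values, rule: str = "median3") -> int:
    """Bin count for histogram features.

    The default takes the median of the Sturges, Scott and
    Freedman-Diaconis counts, which is robust to any single rule
    misbehaving on skewed or heavy-tailed ROI distributions.
    """
    v = np.asarray(values, dtype=float)
    if rule == "sturges":
        return bins_sturges(v.size)
    if rule == "scott":
        return bins_scott(v)
    if rule == "fd":
        return bins_freedman_diaconis(v)
    if rule != "median3":
        raise DomainError(f"unknown histogram rule {rule!r}")
    counts = sorted((bins_sturges(v.size), bins_scott(v), bins_freedman_diaconis(v)))
    return counts[1]


def build_histogram(values, k: int) -> Histogram:
    """k equal-width bins spanning [min, max] of the sample (last bin right-closed)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise EmptyRoiError("cannot build a histogram from an empty sample")
    if k < 1:
        raise DomainError(f"bin count must be >= 1, got {k}")
    counts, edges = np.histogram(v, bins=k)
    probs = counts / v.size
    centers = 0.5 * (edges[:-1] + edges[1:])
    return Histogram(bin_edges=edges, bin_centers=centers, probabilities=probs)


def resample_isotropic(volume: VolumeGrid, mask: RoiMask,
                       target_mm: float | None = None
                       ) -> tuple[VolumeGrid, RoiMask]:
    """Resample volume and mask to cubic voxels.

    The target edge defaults to the minimum input spacing so no axis is
    downsampled.  Intensities are interpolated trilinearly; the mask is
    interpolated as a density and thresholded at 0.5 foreground fraction.
    Before interpolating, out-of-mask voxels are replaced by their nearest
    in-mask value so that background (e.g. 0 % air around a muscle) cannot
    bleed into ROI-boundary intensities — in-mask output values are convex
    combinations of in-mask input values only.
    """
    _check_aligned(volume, mask, "volume and mask")
    sx, sy, sz = volume.spacing
    t = float(min(volume.spacing)) if target_mm is None else float(target_mm)
    if t <= 0:
        raise DomainError("target spacing must be positive")
    # New voxel j sits at physical offset j*t along each axis; stay in bounds.
    new_shape = tuple(int(math.floor((n - 1) * s / t)) + 1
                      for n, s in zip(volume.shape, volume.spacing))
    axes = [np.arange(m) * t / s for m, s in zip(new_shape, volume.spacing)]
    coords = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([c.ravel() for c in coords])
    src = volume.values
    if mask.values.any() and not mask.values.all():
        idx = distance_transform_edt(~mask.values, sampling=volume.spacing,
                                     return_distances=False,
                                     return_indices=True)
        src = src[tuple(idx)]
    vals = map_coordinates(src, coords, order=1, mode="nearest")
    mfrac = map_coordinates(mask.values.astype(np.float64), coords, order=1,
                            mode="nearest")
    vals = vals.reshape(new_shape)
    fg = mfrac.reshape(new_shape) >= 0.5
    if not fg.any():
        raise EmptyRoiError("mask vanished under resampling")
    out_vol = VolumeGrid(values=vals, spacing=(t, t, t), origin=volume.origin,
                         meta=dict(volume.meta))
    out_mask = replace(mask, values=fg, spacing=(t, t, t))
    return out_vol, out_mask


def quantize(volume: VolumeGrid, mask: RoiMask, ng: int = 200,
             bounds: tuple[float, float] | None = None) -> QuantizedRoi:
    """Uniform gray-level quantization of the in-mask intensities.

    Levels are ``min(floor((v - vmin) / (vmax - vmin) * ng) + 1, ng)`` with
    (vmin, vmax) the in-mask extrema by default, or fixed ``bounds``
    (e.g. the full 0-100 % PDFF scale).  A constant ROI maps to level 1.
    """
    _check_aligned(volume, mask, "volume and mask")
    if ng < 1:
        raise DomainError(f"number of gray levels must be >= 1, got {ng}")
    fg = mask.values
    if not fg.any():
        raise EmptyRoiError("cannot quantize an empty ROI")
    v = volume.values[fg]
    if bounds is None:
        vmin, vmax = float(v.min()), float(v.max())
    else:
        vmin, vmax = map(float, bounds)
        if vmax < vmin:
            raise DomainError("bounds must be increasing")
    levels = np.zeros(volume.shape, dtype=np.int32)
    if vmax == vmin:
        levels[fg] = 1
    else:
        lv = np.floor((v - vmin) / (vmax - vmin) * ng).astype(np.int64) + 1
        levels[fg] = np.clip(lv, 1, ng)
    return QuantizedRoi(levels=levels, ng=int(ng), mask=mask,
                        spacing=volume.spacing)
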