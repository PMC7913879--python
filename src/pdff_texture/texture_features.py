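"""First- and second-order texture features of PDFF maps.

First-order ("global") features are moments of the in-ROI intensity
histogram: variance, skewness and non-excess kurtosis (a normal
distribution has kurtosis 3).  They ignore spatial arrangement.

Second-order features come from 3D gray-level co-occurrence matrices
(GLCMs): the joint probability of the quantized levels of two voxels
separated by a fixed offset, accumulated over all in-mask voxel pairs.
The 26-connected neighborhood reduces to 13 offset directions (each
direction and its negation index the same symmetric matrix); features are
computed per direction and averaged over the 13 directions, which makes
the result invariant to grid rotations and reflections.  GLCMs are built
on the isotropically resampled, quantized grid so that unit-voxel offsets
have comparable physical lengths in all 13 directions; no per-direction
distance weighting is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ContractViolation, DegenerateDataError, EmptyRoiError
from .preprocess import (
    Histogram,
    QuantizedRoi,
    TextureConfig,
    build_histogram,
    quantize,
    resample_isotropic,
    select_bin_count,
)
from .volume_io import RoiMask, VolumeGrid, crop_to_mask, extract_roi

__all__ = [
    "DIRECTIONS_13",
    "glcm_directions",
    "Glcm",
    "build_glcm",
    "GlcmFeatures",
    "glcm_features",
    "average_over_directions",
    "GlobalFeatures",
    "global_features",
    "texture_profile",
    "GLOBAL_FEATURE_NAMES",
    "GLCM_FEATURE_NAMES",
    "TEXTURE_FEATURE_NAMES",
]

#: The 13 canonical offsets of the 26-neighborhood under sign inversion,
#: ordered axis offsets first, then face diagonals, then space diagonals.
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

GLOBAL_FEATURE_NAMES = ("variance_global", "skewness_global", "kurtosis_global")
GLCM_FEATURE_NAMES = ("energy", "entropy", "contrast", "homogeneity",
                      "correlation", "variance", "sum_average", "dissimilarity")
TEXTURE_FEATURE_NAMES = GLOBAL_FEATURE_NAMES + GLCM_FEATURE_NAMES


def glcm_directions() -> tuple[tuple[int, int, int], ...]:
    """The 13 co-occurrence offset directions (one per +/- pair of the 26 neighbors)."""
    return DIRECTIONS_13


@dataclass
class Glcm:
    """Symmetric, normalized gray-level co-occurrence matrix for one offset.

    ``pair_count`` is the number of ordered in-mask voxel pairs counted
    before symmetrization; ``pair_count == 0`` flags a direction with no
    valid pair (skipped when averaging).
    """

    p: np.ndarray
    offset: tuple[int, int, int]
    pair_count: int


@dataclass
class GlcmFeatures:
    """The eight co-occurrence features, on the quantized-level scale."""

    energy: float
    entropy: float
    contrast: float
    homogeneity: float
    correlation: float
    variance: float
    sum_average: float
    dissimilarity: float
    correlation_degenerate: bool = False

    def as_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in GLCM_FEATURE_NAMES}


@dataclass
class GlobalFeatures:
    """First-order histogram moments (variance in %^2; kurtosis non-excess)."""

    variance_global: float
    skewness_global: float
    kurtosis_global: float
    degenerate: bool = False

    def as_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in GLOBAL_FEATURE_NAMES}


def build_glcm(q: QuantizedRoi, offset: tuple[int, int, int]) -> Glcm:
    """Accumulate co-occurrences of in-mask level pairs at ``offset``.

    Counts every ordered pair (v, v + offset) with both voxels inside the
    mask, then symmetrizes by adding the transpose and normalizes to sum 1.
    """
    dx, dy, dz = offset
    lev, fg, ng = q.levels, q.mask.values, q.ng
    shp = lev.shape

    def _sl(d, n):
        # source / destination slices along one axis for displacement d
        if d >= 0:
            return slice(0, n - d), slice(d, n)
        return slice(-d, n), slice(0, n + d)

    sx, tx = _sl(dx, shp[0])
    sy, ty = _sl(dy, shp[1])
    sz, tz = _sl(dz, shp[2])
    a = lev[sx, sy, sz]
    b = lev[tx, ty, tz]
    valid = fg[sx, sy, sz] & fg[tx, ty, tz]
    i = a[valid] - 1
    j = b[valid] - 1
    n_pairs = int(valid.sum())
    if n_pairs == 0:
        return Glcm(p=np.zeros((ng, ng)), offset=tuple(offset), pair_count=0)
    counts = np.bincount(i * ng + j, minlength=ng * ng).reshape(ng, ng)
    sym = counts + counts.T
    p = sym / sym.sum()
    return Glcm(p=p, offset=tuple(offset), pair_count=n_pairs)


def glcm_features(g: Glcm, log_base: float = 2.0) -> GlcmFeatures:
    """Second-order features of one normalized co-occurrence matrix.

    energy      sum p^2
    entropy     -sum p log(p), base 2 by default (bits)
    contrast    sum (i-j)^2 p
    homogeneity sum p / (1 + |i-j|)
    correlation sum (i-mu)(j-mu) p / sigma^2, mu/sigma^2 the marginal
                mean/variance of the symmetric matrix; defined as 0
                (flagged) when sigma^2 = 0
    variance    sum (i-mu)^2 p
    sum_average sum_k k p_{x+y}(k), k = 2..2*Ng
    dissimilarity sum |i-j| p
    """
    if g.pair_count == 0:
        raise DegenerateDataError("cannot compute features of a skipped direction")
    p = g.p
    total = p.sum()
    if not np.isclose(total, 1.0, atol=1e-8):
        raise ContractViolation(f"GLCM not normalized (sum = {total})")
    ng = p.shape[0]
    idx = np.arange(1, ng + 1, dtype=float)
    px = p.sum(axis=1)                       # marginal (== column marginal)
    mu = float(idx @ px)
    sigma2 = float(((idx - mu) ** 2) @ px)

    energy = float((p * p).sum())
    nz = p[p > 0]
    entropy = float(-(nz * (np.log(nz) / np.log(log_base))).sum())

    diff = np.abs(idx[:, None] - idx[None, :])
    contrast = float(((diff ** 2) * p).sum())
    homogeneity = float((p / (1.0 + diff)).sum())
    dissimilarity = float((diff * p).sum())

    degenerate = sigma2 <= 0.0
    if degenerate:
        correlation = 0.0
    else:
        dev = idx - mu
        correlation = float((dev[:, None] * dev[None, :] * p).sum() / sigma2)

    # p_{x+y}: distribution of i+j, k = 2..2*ng
    ksum = (np.arange(ng)[:, None] + np.arange(ng)[None, :]).ravel()
    pxy = np.bincount(ksum, weights=p.ravel(), minlength=2 * ng - 1)
    kvals = np.arange(2, 2 * ng + 1, dtype=float)
    sum_average = float(kvals @ pxy)

    return GlcmFeatures(energy=energy, entropy=entropy, contrast=contrast,
                        homogeneity=homogeneity, correlation=correlation,
                        variance=sigma2, sum_average=sum_average,
                        dissimilarity=dissimilarity,
                        correlation_degenerate=degenerate)


def average_over_directions(per_direction: list[GlcmFeatures]) -> GlcmFeatures:
    """Unweighted mean of each feature over the non-skipped directions.

    Averaging over all 13 directions is what makes the reported features
    rotation invariant.
    """
    if len(per_direction) == 0:
        raise DegenerateDataError("no direction produced a valid co-occurrence matrix")
    vals = {n: float(np.mean([getattr(f, n) for f in per_direction]))
            for n in GLCM_FEATURE_NAMES}
    flag = any(f.correlation_degenerate for f in per_direction)
    return GlcmFeatures(**vals, correlation_degenerate=flag)


def global_features(h: Histogram) -> GlobalFeatures:
    """Histogram moments about the probability-weighted mean of bin centers.

    variance = m2, skewness = m3 / m2^1.5, kurtosis = m4 / m2^2
    (non-excess).  A zero-variance histogram yields skewness and kurtosis
    0 with the degenerate flag set.
    """
    p = np.asarray(h.probabilities, dtype=float)
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ContractViolation(f"histogram not normalized (sum = {p.sum()})")
    c = np.asarray(h.bin_centers, dtype=float)
    mean = float(p @ c)
    d = c - mean
    m2 = float(p @ d ** 2)
    if m2 <= 0.0:
        return GlobalFeatures(0.0, 0.0, 0.0, degenerate=True)
    m3 = float(p @ d ** 3)
    m4 = float(p @ d ** 4)
    return GlobalFeatures(variance_global=m2,
                          skewness_global=m3 / m2 ** 1.5,
                          kurtosis_global=m4 / m2 ** 2)


def glcm_profile(volume: VolumeGrid, mask: RoiMask,
                 config: TextureConfig = TextureConfig()
                 ) -> tuple[GlcmFeatures, int]:
    """Direction-averaged co-occurrence features for one ROI.

    Crops to the mask bounding box, resamples isotropically, quantizes,
    builds the 13 per-direction GLCMs and averages their features.
    Returns the averaged features and the number of skipped directions.
    """
    cvol, cmask = crop_to_mask(volume, mask)
    rvol, rmask = resample_isotropic(cvol, cmask, config.isotropic_mm)
    bounds = None if config.intensity_bounds == "roi" else tuple(config.intensity_bounds)
    q = quantize(rvol, rmask, ng=config.ng_levels, bounds=bounds)
    feats = []
    skipped = 0
    for off in DIRECTIONS_13:
        g = build_glcm(q, off)
        if g.pair_count == 0:
            skipped += 1
            continue
        feats.append(glcm_features(g, log_base=config.entropy_log_base))
    return average_over_directions(feats), skipped


def texture_profile(volume: VolumeGrid, mask: RoiMask,
                    config: TextureConfig = TextureConfig()):
    """Full per-muscle feature set: mean PDFF, volume, and the 11 features.

    First-order features come from the original-resolution in-mask voxels
    (bin count by the configured rule); co-occurrence features from the
    resampled, quantized grid via :func:`glcm_profile`.
    """
    from .cohort_features import MuscleFeatureSet  # local import, no cycle at module load

    sample = extract_roi(volume, mask)
    k = select_bin_count(sample.voxel_values, rule=config.histogram_rule) \
        if sample.voxel_count >= 2 else 1
    hist = build_histogram(sample.voxel_values, k)
    gf = global_features(hist)
    cf, skipped = glcm_profile(volume, mask, config)
    features = {**gf.as_dict(), **cf.as_dict()}
    return MuscleFeatureSet(muscle=mask.muscle, side=mask.side,
                            mean_pdff=float(np.mean(sample.voxel_values)),
                            physical_volume=sample.physical_volume,
                            voxel_count=sample.voxel_count,
                            features=features,
                            skipped_directions=skipped,
                            degenerate=gf.degenerate or cf.correlation_degenerate)
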