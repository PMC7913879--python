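"""Independent brute-force oracles for co-occurrence computations.

Everything here is written as explicit Python loops over voxels and matrix
entries, deliberately sharing no code with the package implementation.
"""

import math

import numpy as np


def brute_glcm(levels, mask, offset, ng):
    """Enumerate every in-mask ordered voxel pair at ``offset``.

    Returns (symmetric normalized matrix or None if no pair, pair_count).
    """
    nx, ny, nz = levels.shape
    dx, dy, dz = offset
    counts = [[0] * ng for _ in range(ng)]
    pairs = 0
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                u, v, w = x + dx, y + dy, z + dz
                if not (0 <= u < nx and 0 <= v < ny and 0 <= w < nz):
                    continue
                if not mask[u, v, w]:
                    continue
                counts[levels[x, y, z] - 1][levels[u, v, w] - 1] += 1
                pairs += 1
    if pairs == 0:
        return None, 0
    sym = [[counts[i][j] + counts[j][i] for j in range(ng)] for i in range(ng)]
    total = sum(sum(row) for row in sym)
    p = np.array([[sym[i][j] / total for j in range(ng)] for i in range(ng)])
    return p, pairs


def brute_glcm_features(p):
    """Feature formulas evaluated entry by entry (entropy in bits)."""
    ng = p.shape[0]
    px = [sum(p[i][j] for j in range(ng)) for i in range(ng)]
    mu = sum((i + 1) * px[i] for i in range(ng))
    sigma2 = sum((i + 1 - mu) ** 2 * px[i] for i in range(ng))
    energy = entropy = contrast = homogeneity = dissimilarity = 0.0
    corr_num = 0.0
    sum_average = 0.0
    pxy = [0.0] * (2 * ng + 1)  # index by level sum k = 2..2ng
    for i in range(ng):
        for j in range(ng):
            q = p[i][j]
            energy += q * q
            if q > 0:
                entropy -= q * math.log2(q)
            d = abs(i - j)
            contrast += d * d * q
            homogeneity += q / (1 + d)
            dissimilarity += d * q
            corr_num += (i + 1 - mu) * (j + 1 - mu) * q
            pxy[i + j + 2] += q
    for k in range(2, 2 * ng + 1):
        sum_average += k * pxy[k]
    correlation = corr_num / sigma2 if sigma2 > 0 else 0.0
    return {
        "energy": energy,
        "entropy": entropy,
        "contrast": contrast,
        "homogeneity": homogeneity,
        "correlation": correlation,
        "variance": sigma2,
        "sum_average": sum_average,
        "dissimilarity": dissimilarity,
    }


def random_masked_grid(rng, max_dim=8, max_ng=6):
    """A random quantized ROI: random shape, ~70 % mask coverage, levels 1..ng."""
    shape = tuple(int(rng.integers(2, max_dim + 1)) for _ in range(3))
    ng = int(rng.integers(2, max_ng + 1))
    mask = rng.random(shape) < 0.7
    if not mask.any():
        mask[0, 0, 0] = True
    levels = np.zeros(shape, dtype=np.int32)
    levels[mask] = rng.integers(1, ng + 1, size=int(mask.sum()))
    return levels, mask, ng
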