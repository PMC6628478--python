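"""Gray-level co-occurrence matrix (GLCM) texture features in 3D.

Lesion intensities are quantized to a fixed number of gray levels (min-max
over the lesion), a single symmetric co-occurrence matrix is pooled over the
13 unique 3D offsets at distance 1 (voxel pairs must both lie inside the
mask), and the 14 classical Haralick statistics are computed from the pooled
matrix.  Pooling into one matrix, rather than averaging per-offset features,
keeps estimates stable for small lesions.
"""

from __future__ import annotations

import warnings

import numpy as np

#: the 13 unique nearest-neighbour offsets in 3D (half of the 26-neighbourhood)
OFFSETS_3D = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
    (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]

TEXTURE_NAMES = [
    "energy", "contrast", "correlation", "homogeneity", "entropy",
    "sum_average", "sum_variance", "sum_entropy", "difference_variance",
    "difference_entropy", "imc1", "imc2", "max_correlation_coefficient",
    "variance",
]


def quantize(values: np.ndarray, n_levels: int = 32) -> np.ndarray:
    """Min-max quantize to integer levels 0..n_levels-1.

    A constant input maps to level 0 everywhere.
    """
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros(values.shape, dtype=np.intp)
    q = np.floor((values - lo) / (hi - lo) * n_levels).astype(np.intp)
    return np.minimum(q, n_levels - 1)


def glcm_pooled(
    image: np.ndarray,
    mask: np.ndarray,
    n_levels: int = 32,
    offsets: list[tuple[int, int, int]] | None = None,
) -> np.ndarray:
    """Symmetric, normalized GLCM pooled over offsets, masked pairs only."""
    if offsets is None:
        offsets = OFFSETS_3D
    mask = mask.astype(bool)
    quant = np.zeros(image.shape, dtype=np.intp)
    quant[mask] = quantize(np.asarray(image, dtype=float)[mask], n_levels)

    counts = np.zeros((n_levels, n_levels), dtype=np.float64)
    for off in offsets:
        src = tuple(
            slice(max(0, -o), image.shape[ax] - max(0, o))
            for ax, o in enumerate(off)
        )
        dst = tuple(
            slice(max(0, o), image.shape[ax] + min(0, o))
            for ax, o in enumerate(off)
        )
        pair_ok = mask[src] & mask[dst]
        i = quant[src][pair_ok]
        j = quant[dst][pair_ok]
        np.add.at(counts, (i, j), 1.0)
        np.add.at(counts, (j, i), 1.0)  # symmetric accumulation
    total = counts.sum()
    if total == 0:
        raise ValueError("no co-occurring voxel pairs inside the mask")
    return counts / total


def haralick_features(p: np.ndarray) -> dict[str, float]:
    """The 14 Haralick statistics of a normalized symmetric GLCM.

    For a degenerate (single-level) matrix, energy is 1, entropy and contrast
    are 0, and correlation-type features are returned as NaN with a warning.
    """
    p = np.asarray(p, dtype=float)
    ng = p.shape[0]
    levels = np.arange(ng, dtype=float)
    ii, jj = np.meshgrid(levels, levels, indexing="ij")

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((levels * px).sum())
    mu_y = float((levels * py).sum())
    sd_x = float(np.sqrt(((levels - mu_x) ** 2 * px).sum()))
    sd_y = float(np.sqrt(((levels - mu_y) ** 2 * py).sum()))

    # distributions of i+j (0..2ng-2) and |i-j| (0..ng-1)
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel(), p.ravel())
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), p.ravel())
    k_sum = np.arange(2 * ng - 1, dtype=float)
    k_diff = np.arange(ng, dtype=float)

    def _entropy(q: np.ndarray) -> float:
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum())

    out: dict[str, float] = {}
    out["energy"] = float((p**2).sum())
    out["contrast"] = float(((ii - jj) ** 2 * p).sum())
    degenerate = sd_x == 0 or sd_y == 0
    if degenerate:
        warnings.warn(
            "GLCM is degenerate (single gray level); correlation-type "
            "features are undefined and reported as missing",
            stacklevel=2,
        )
        out["correlation"] = np.nan
    else:
        out["correlation"] = float(((ii * jj * p).sum() - mu_x * mu_y) / (sd_x * sd_y))
    out["homogeneity"] = float((p / (1.0 + (ii - jj) ** 2)).sum())
    out["entropy"] = _entropy(p.ravel())
    out["sum_average"] = float((k_sum * p_sum).sum())
    out["sum_variance"] = float(((k_sum - out["sum_average"]) ** 2 * p_sum).sum())
    out["sum_entropy"] = _entropy(p_sum)
    mu_diff = float((k_diff * p_diff).sum())
    out["difference_variance"] = float(((k_diff - mu_diff) ** 2 * p_diff).sum())
    out["difference_entropy"] = _entropy(p_diff)

    hxy = out["entropy"]
    hx = _entropy(px)
    hy = _entropy(py)
    pxpy = np.outer(px, py)
    valid = (p > 0) & (pxpy > 0)
    hxy1 = float(-(p[valid] * np.log2(pxpy[valid])).sum())
    pos = pxpy > 0
    hxy2 = float(-(pxpy[pos] * np.log2(pxpy[pos])).sum())
    denom = max(hx, hy)
    out["imc1"] = float((hxy - hxy1) / denom) if denom > 0 else np.nan
    out["imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    out["max_correlation_coefficient"] = _max_correlation(p, px, py)
    if degenerate:
        out["variance"] = 0.0
    else:
        out["variance"] = float(((ii - mu_x) ** 2 * p).sum())
    return out


def _max_correlation(p: np.ndarray, px: np.ndarray, py: np.ndarray) -> float:
    """sqrt of the second-largest eigenvalue of Q(i,j)=sum_k p_ik p_jk/(px_i py_k)."""
    keep = (px > 0) & (py > 0)
    if keep.sum() < 2:
        return np.nan
    pr = p[np.ix_(keep, keep)]
    pxr = px[keep]
    pyr = py[keep]
    q = (pr / pxr[:, None]) @ (pr / pyr[None, :]).T
    try:
        eig = np.linalg.eigvals(q)
    except np.linalg.LinAlgError:
        return np.nan
    eig = np.sort(np.real(eig))[::-1]
    second = max(0.0, float(eig[1]))
    return float(np.sqrt(min(second, 1.0)))


def compute_texture(
    image: np.ndarray,
    mask: np.ndarray,
    n_levels: int = 32,
) -> dict[str, float]:
    """GLCM texture features (T1..T14) of a masked 3D image."""
    p = glcm_pooled(image, mask, n_levels=n_levels)
    return haralick_features(p)
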