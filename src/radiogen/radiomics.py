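"""The 38 quantitative DCE-MRI lesion phenotypes in six categories.

Categories and counts: size S1-S4, shape G1-G3, morphology M1-M3,
enhancement texture T1-T14, kinetic curve assessment K1-K10, and
enhancement-variance kinetics V1-V4.  ``extract_all`` concatenates the six
category computations into a single named 38-vector;
``normalize_features`` z-scores a cohort feature table column-wise.

Relative enhancement E_t(x) = (S_t(x) - S_0(x)) / (S_0(x) + eps) is the
shared primitive: segmentation clusters it, texture quantizes the first
post-contrast frame, and kinetics summarize its time course.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull
from skimage import measure

from . import texture as _texture
from .phantom import DceMriSeries

#: relative guard against division by zero in the enhancement map
EPS_FRACTION = 1e-6

SIZE_NAMES = ["S1_volume", "S2_effective_diameter", "S3_surface_area",
              "S4_maximum_linear_size"]
SHAPE_NAMES = ["G1_sphericity", "G2_irregularity", "G3_surface_to_volume_ratio"]
MORPHOLOGY_NAMES = ["M1_margin_sharpness", "M2_variance_of_margin_sharpness",
                    "M3_variance_of_radial_gradient_histogram"]
TEXTURE_NAMES = [f"T{i + 1}_{name}" for i, name in enumerate(_texture.TEXTURE_NAMES)]
KINETIC_NAMES = [
    "K1_maximum_enhancement", "K2_time_to_peak", "K3_uptake_rate",
    "K4_washout_rate", "K5_curve_shape_index",
    "K6_enhancement_at_first_postcontrast", "K7_signal_enhancement_ratio",
    "K8_volume_of_most_enhancing_voxels", "K9_total_rate_variation",
    "K10_normalized_total_rate_variation",
]
VARIANCE_KINETIC_NAMES = [
    "V1_maximum_variance_of_enhancement", "V2_time_to_peak_of_variance",
    "V3_variance_increase_rate", "V4_variance_decrease_rate",
]

FEATURE_NAMES = (SIZE_NAMES + SHAPE_NAMES + MORPHOLOGY_NAMES + TEXTURE_NAMES
                 + KINETIC_NAMES + VARIANCE_KINETIC_NAMES)

CATEGORIES = {
    "size": SIZE_NAMES,
    "shape": SHAPE_NAMES,
    "morphology": MORPHOLOGY_NAMES,
    "enhancement_texture": TEXTURE_NAMES,
    "kinetic_curve": KINETIC_NAMES,
    "enhancement_variance_kinetics": VARIANCE_KINETIC_NAMES,
}

assert len(FEATURE_NAMES) == 38


@dataclass(frozen=True)
class RadiomicsParams:
    """Tunable extraction parameters (defaults documented in docs/methods.md)."""

    glcm_levels: int = 32
    texture_frame_index: int = 1
    most_enhancing_quantile: float = 0.9
    radial_histogram_bins: int = 20
    normal_smoothing_sigma_mm: float = 1.5


def compute_enhancement_map(series: DceMriSeries, frame_index: int) -> np.ndarray:
    """Relative enhancement E_t = (S_t - S_0) / (S_0 + eps), elementwise."""
    if not 1 <= frame_index < series.frames.shape[0]:
        raise ValueError(
            f"frame_index must be in [1, {series.frames.shape[0] - 1}], "
            f"got {frame_index}"
        )
    s0 = series.frames[0]
    st = series.frames[frame_index]
    eps = EPS_FRACTION * float(np.abs(series.frames).max())
    return (st - s0) / (s0 + eps)


# ---------------------------------------------------------------------------
# size (S) and shape (G)


def compute_size_features(mask: np.ndarray, spacing: tuple[float, float, float]
                          ) -> dict[str, float]:
    mask = mask.astype(bool)
    n_vox = int(mask.sum())
    if n_vox == 0:
        raise ValueError("empty mask")
    voxvol = float(np.prod(spacing))
    s1 = n_vox * voxvol
    s2 = (6.0 * s1 / np.pi) ** (1.0 / 3.0)
    s3 = _surface_area(mask, spacing)
    s4 = _maximum_linear_size(mask, spacing)
    return dict(zip(SIZE_NAMES, [s1, s2, s3, s4]))


def _surface_area(mask: np.ndarray, spacing) -> float:
    """Isosurface area at level 0.5 of the lightly smoothed binary mask.

    Mild Gaussian smoothing before marching cubes suppresses the staircase
    bias of a raw binary isosurface (a digital sphere would otherwise read
    several percent high).
    """
    padded = np.pad(mask.astype(float), 2)
    # sigma 0.6 of the finest voxel pitch: enough to suppress staircase
    # facets while keeping the (small, positive) area bias of the binary
    # isosurface, so sphericity of a digital sphere stays just below 1
    sigma_vox = [0.6 * min(spacing) / s for s in spacing]
    smoothed = ndimage.gaussian_filter(padded, sigma=sigma_vox)
    if smoothed.max() <= 0.5:
        # tiny masks can be smoothed entirely below the isolevel; fall back
        # to the raw binary isosurface
        smoothed = padded
    verts, faces, _, _ = measure.marching_cubes(smoothed, level=0.5, spacing=spacing)
    return float(measure.mesh_surface_area(verts, faces))


def _maximum_linear_size(mask: np.ndarray, spacing) -> float:
    """Greatest distance (mm) between surface voxel centres."""
    eroded = ndimage.binary_erosion(mask)
    surface = mask & ~eroded
    pts = np.argwhere(surface) * np.asarray(spacing)
    if len(pts) == 1:
        return 0.0
    if len(pts) > 4:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except Exception:  # degenerate (coplanar) point sets
            pass
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=-1)
    return float(np.sqrt(d2.max()))


def compute_shape_features(mask: np.ndarray, spacing) -> dict[str, float]:
    s = compute_size_features(mask, spacing)
    s1, s3 = s["S1_volume"], s["S3_surface_area"]
    g1 = np.pi ** (1.0 / 3.0) * (6.0 * s1) ** (2.0 / 3.0) / s3
    # discretization can push the ratio marginally past the isoperimetric
    # bound; sphericity is capped at its theoretical maximum
    g1 = min(g1, 1.0)
    return dict(zip(SHAPE_NAMES, [g1, 1.0 - g1, s3 / s1]))


# ---------------------------------------------------------------------------
# morphology (M)


def compute_morphology_features(
    series: DceMriSeries,
    mask: np.ndarray,
    params: RadiomicsParams = RadiomicsParams(),
) -> dict[str, float]:
    """Margin sharpness (M1, M2) and radial gradient histogram variance (M3).

    M1 is the mean over boundary voxels of the magnitude of the enhancement
    gradient projected onto the outward surface normal; M2 its variance.
    Normals come from the negative gradient of a Gaussian-smoothed mask.
    Boundary voxels on the volume border lack outward neighbours and are
    skipped with a warning.
    """
    mask = mask.astype(bool)
    spacing = np.asarray(series.spacing)
    emap = compute_enhancement_map(series, frame_index=1)
    grad = np.stack(np.gradient(emap, *spacing), axis=-1)

    boundary = mask & ~ndimage.binary_erosion(mask)
    if not boundary.any():
        raise ValueError("mask has no boundary shell")

    border = np.zeros_like(mask)
    border[0, :, :] = border[-1, :, :] = True
    border[:, 0, :] = border[:, -1, :] = True
    border[:, :, 0] = border[:, :, -1] = True
    skipped = boundary & border
    if skipped.any():
        warnings.warn(
            f"{int(skipped.sum())} boundary voxels touch the volume border "
            "and are skipped in margin sharpness",
            stacklevel=2,
        )
        boundary = boundary & ~border

    sigma_vox = params.normal_smoothing_sigma_mm / spacing
    smooth_mask = ndimage.gaussian_filter(mask.astype(float), sigma=sigma_vox)
    normal = -np.stack(np.gradient(smooth_mask, *spacing), axis=-1)
    norms = np.linalg.norm(normal, axis=-1, keepdims=True)
    normal = np.divide(normal, norms, out=np.zeros_like(normal), where=norms > 0)

    directional = np.abs((grad * normal).sum(axis=-1))[boundary]
    m1 = float(directional.mean())
    m2 = float(directional.var())

    # radial gradient projections over the whole lesion
    centroid = np.asarray(ndimage.center_of_mass(mask))
    coords = np.argwhere(mask).astype(float)
    radial = (coords - centroid) * spacing
    rnorm = np.linalg.norm(radial, axis=1, keepdims=True)
    rhat = np.divide(radial, rnorm, out=np.zeros_like(radial), where=rnorm > 0)
    proj = (grad[mask] * rhat).sum(axis=1)
    hist, _ = np.histogram(proj, bins=params.radial_histogram_bins)
    hist = hist / hist.sum()
    m3 = float(hist.var())
    return dict(zip(MORPHOLOGY_NAMES, [m1, m2, m3]))


# ---------------------------------------------------------------------------
# texture (T)


def compute_texture_features(
    series: DceMriSeries,
    mask: np.ndarray,
    params: RadiomicsParams = RadiomicsParams(),
) -> dict[str, float]:
    """Haralick features of the first post-contrast frame within the lesion."""
    image = series.frames[params.texture_frame_index]
    feats = _texture.compute_texture(image, mask, n_levels=params.glcm_levels)
    return {name: feats[raw] for name, raw in zip(TEXTURE_NAMES,
                                                  _texture.TEXTURE_NAMES)}


# ---------------------------------------------------------------------------
# kinetics (K) and enhancement-variance kinetics (V)


def _mean_enhancement_curve(
    series: DceMriSeries, subregion: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(post-contrast times, mean enhancement over the subregion per frame)."""
    times = np.asarray(series.frame_times[1:])
    curve = np.array([
        float(compute_enhancement_map(series, t)[subregion].mean())
        for t in range(1, series.frames.shape[0])
    ])
    return times, curve


def most_enhancing_subregion(
    series: DceMriSeries, mask: np.ndarray, quantile: float = 0.9
) -> np.ndarray:
    """Voxels whose first-post-contrast enhancement is in the top decile."""
    e1 = compute_enhancement_map(series, 1)
    vals = e1[mask]
    thresh = np.quantile(vals, quantile)
    sub = mask & (e1 >= thresh)
    if not sub.any():  # all-equal enhancement: fall back to the whole lesion
        sub = mask.copy()
    return sub


def compute_kinetic_features(
    series: DceMriSeries,
    mask: np.ndarray,
    params: RadiomicsParams = RadiomicsParams(),
) -> dict[str, float]:
    """K1..K10 from the characteristic curve of the most-enhancing subregion."""
    sub = most_enhancing_subregion(series, mask, params.most_enhancing_quantile)
    times, curve = _mean_enhancement_curve(series, sub)
    t_last = times[-1]

    peak_idx = int(np.argmax(curve))
    k1 = float(curve[peak_idx])
    k2 = float(times[peak_idx])
    k3 = k1 / k2 if k2 > 0 else np.nan
    e_last = float(curve[-1])
    if k2 < t_last and k1 != 0:
        k4 = (k1 - e_last) / ((t_last - k2) * k1)
    else:
        k4 = 0.0
    k5 = float(np.clip((e_last - k1) / k1 if k1 != 0 else 0.0, -1.0, 1.0))
    k6 = float(curve[0])
    if e_last == 0:
        warnings.warn("last-frame enhancement is 0; signal enhancement ratio "
                      "is undefined", stacklevel=2)
        k7 = np.nan
    else:
        k7 = k6 / e_last
    k8 = float(sub.sum()) * series.voxel_volume
    dt = np.diff(times)
    de = np.diff(curve)
    k9 = float(((de / dt) ** 2 * dt).sum())
    denom = float((curve[1:] ** 2 * dt).sum())
    k10 = k9 / denom if denom > 0 else np.nan
    return dict(zip(KINETIC_NAMES, [k1, k2, k3, k4, k5, k6, k7, k8, k9, k10]))


def compute_variance_kinetic_features(
    series: DceMriSeries, mask: np.ndarray
) -> dict[str, float]:
    """V1..V4 from the time course of within-lesion enhancement variance."""
    mask = mask.astype(bool)
    if mask.sum() == 1:
        warnings.warn("single-voxel mask: enhancement variance is 0 at all "
                      "frames", stacklevel=2)
    times = np.asarray(series.frame_times[1:])
    var_t = np.array([
        float(compute_enhancement_map(series, t)[mask].var())
        for t in range(1, series.frames.shape[0])
    ])
    peak_idx = int(np.argmax(var_t))
    v1 = float(var_t[peak_idx])
    v2 = float(times[peak_idx])
    v3 = v1 / v2 if v2 > 0 else np.nan
    t_last = times[-1]
    if v2 < t_last and v1 > 0:
        v4 = (v1 - float(var_t[-1])) / ((t_last - v2) * v1)
    else:
        v4 = 0.0
    return dict(zip(VARIANCE_KINETIC_NAMES, [v1, v2, v3, v4]))


# ---------------------------------------------------------------------------
# assembly and normalization


def extract_all(
    series: DceMriSeries,
    mask: np.ndarray,
    params: RadiomicsParams = RadiomicsParams(),
) -> pd.Series:
    """All 38 phenotypes as a named Series (missing values are NaN, flagged
    by a warning at computation time, never dropped)."""
    out: dict[str, float] = {}
    out.update(compute_size_features(mask, series.spacing))
    out.update(compute_shape_features(mask, series.spacing))
    out.update(compute_morphology_features(series, mask, params))
    out.update(compute_texture_features(series, mask, params))
    out.update(compute_kinetic_features(series, mask, params))
    out.update(compute_variance_kinetic_features(series, mask))
    vec = pd.Series(out, dtype=float).reindex(FEATURE_NAMES)
    assert len(vec) == 38
    return vec


def normalize_features(table: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Z-score each feature column to zero mean, unit variance (sample SD).

    Returns the normalized table and the list of zero-variance columns, which
    are set to 0 rather than divided by 0.
    """
    if len(table) < 2:
        raise ValueError("need >= 2 cases to normalize")
    mean = table.mean(axis=0, skipna=True)
    sd = table.std(axis=0, ddof=1, skipna=True)
    flagged = [c for c in table.columns if not sd[c] > 0]
    safe_sd = sd.where(sd > 0, 1.0)
    z = (table - mean) / safe_sd
    z[flagged] = 0.0
    return z, flagged
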