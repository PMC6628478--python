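"""Seed-point lesion segmentation via fuzzy c-means on contrast enhancement.

A single operator-provided seed voxel is the only input.  Within a cubic
region of interest around the seed, voxels are clustered on their relative
enhancement at the first post-contrast frame using fuzzy c-means (FCM); the
lesion is the connected component of high-enhancement-cluster voxels that
contains (or is nearest to) the seed, after hole filling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import DceMriSeries
from .radiomics import compute_enhancement_map


class NoLesionFoundError(RuntimeError):
    """Raised when no candidate lesion voxels survive thresholding."""


@dataclass(frozen=True)
class SeedPoint:
    """Operator seed: voxel coordinates on the series grid."""

    position: tuple[int, int, int]


@dataclass(frozen=True)
class SegmentationParams:
    roi_half_width_mm: float = 20.0
    n_clusters: int = 2
    fuzzifier: float = 2.0
    membership_threshold: float = 0.5
    convergence_tol: float = 1e-5
    max_iter: int = 300

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if not 0 < self.membership_threshold < 1:
            raise ValueError("membership_threshold must be in (0, 1)")
        if self.fuzzifier <= 1:
            raise ValueError("fuzzifier must be > 1")


def fcm_cluster(
    values: np.ndarray,
    n_clusters: int = 2,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    rng_seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fuzzy c-means on a 1D feature vector.

    Minimizes J = sum_ik u_ik^m (x_k - c_i)^2 by alternating the classical
    membership and centre updates.  Initialization is deterministic (centres
    at evenly spaced percentiles, 10th..90th); ``rng_seed`` switches to random
    membership initialization, used only by randomized-restart checks.

    Returns
    -------
    memberships : (n_points, n_clusters), rows sum to 1; columns ordered by
        ascending cluster centre.
    centers : (n_clusters,) ascending.
    """
    x = np.asarray(values, dtype=float).ravel()
    if np.unique(x).size < n_clusters:
        raise ValueError(
            f"need >= {n_clusters} distinct values for {n_clusters} clusters"
        )

    if rng_seed is None:
        # spread initial centres across the full value range: a lesion is a
        # small high-enhancement mode, so quantile-based initialization can
        # place every centre inside the dominant background mode
        centers = np.linspace(x.min(), x.max(), n_clusters)
        # perturb exact ties between initial centres
        for i in range(1, n_clusters):
            if centers[i] <= centers[i - 1]:
                centers[i] = centers[i - 1] + 1e-9 * (1 + abs(centers[i - 1]))
        u = _memberships(x, centers, m)
    else:
        rng = np.random.Generator(np.random.PCG64(rng_seed))
        u = rng.dirichlet(np.ones(n_clusters), size=x.size)
        centers = _centers(x, u, m)
        u = _memberships(x, centers, m)

    prev_obj = np.inf
    for _ in range(max_iter):
        centers = _centers(x, u, m)
        u = _memberships(x, centers, m)
        obj = float(np.sum(u**m * (x[:, None] - centers[None, :]) ** 2))
        if prev_obj - obj <= tol * max(1.0, abs(prev_obj)):
            break
        prev_obj = obj

    order = np.argsort(centers)
    return u[:, order], centers[order]


def _centers(x: np.ndarray, u: np.ndarray, m: float) -> np.ndarray:
    w = u**m
    return (w * x[:, None]).sum(axis=0) / w.sum(axis=0)


def _memberships(x: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    d2 = (x[:, None] - centers[None, :]) ** 2
    # exact hits: full membership to the (first) zero-distance cluster
    zero = d2 <= 0
    d2 = np.where(zero, 1.0, d2)
    inv = d2 ** (-1.0 / (m - 1))
    u = inv / inv.sum(axis=1, keepdims=True)
    hit_rows = zero.any(axis=1)
    if np.any(hit_rows):
        u[hit_rows] = 0.0
        first_hit = np.argmax(zero[hit_rows], axis=1)
        u[np.nonzero(hit_rows)[0], first_hit] = 1.0
    return u


def fcm_objective(values: np.ndarray, memberships: np.ndarray,
                  centers: np.ndarray, m: float = 2.0) -> float:
    x = np.asarray(values, dtype=float).ravel()
    return float(np.sum(memberships**m * (x[:, None] - centers[None, :]) ** 2))


def segment_lesion(
    series: DceMriSeries,
    seed: SeedPoint,
    params: SegmentationParams = SegmentationParams(),
) -> np.ndarray:
    """Segment the lesion containing the seed point; returns a boolean mask.

    Enhancement is relative, so the result is invariant to global intensity
    scaling of the series.
    """
    pos = tuple(int(p) for p in seed.position)
    shape = series.grid_shape
    for ax in range(3):
        if not 0 <= pos[ax] < shape[ax]:
            raise ValueError(f"seed {pos} outside grid {shape}")

    # cubic ROI around the seed, half-width in mm converted per axis
    half = [
        max(1, int(round(params.roi_half_width_mm / series.spacing[ax])))
        for ax in range(3)
    ]
    lo = [max(0, pos[ax] - half[ax]) for ax in range(3)]
    hi = [min(shape[ax], pos[ax] + half[ax] + 1) for ax in range(3)]
    roi = tuple(slice(lo[ax], hi[ax]) for ax in range(3))

    # clustering feature: mean relative enhancement over the post-contrast
    # frames — averaging suppresses acquisition noise that a single frame
    # retains, which matters for small, weakly enhancing lesions
    emap = np.mean(
        [compute_enhancement_map(series, t)[roi]
         for t in range(1, series.frames.shape[0])],
        axis=0,
    )
    try:
        u, centers = fcm_cluster(
            emap.ravel(),
            n_clusters=params.n_clusters,
            m=params.fuzzifier,
            tol=params.convergence_tol,
            max_iter=params.max_iter,
        )
    except ValueError as err:
        raise NoLesionFoundError(f"degenerate ROI: {err}") from err

    # highest-enhancement cluster is the last column (centres ascending)
    candidates = (u[:, -1] >= params.membership_threshold).reshape(emap.shape)
    if not candidates.any():
        raise NoLesionFoundError("no voxels assigned to the lesion cluster")

    labels, n_comp = ndimage.label(candidates, structure=np.ones((3, 3, 3), int))
    seed_local = tuple(pos[ax] - lo[ax] for ax in range(3))
    lab = labels[seed_local]
    if lab == 0:
        # nearest candidate component by centroid distance to the seed (mm)
        centroids = ndimage.center_of_mass(candidates, labels, range(1, n_comp + 1))
        spacing = np.asarray(series.spacing)
        dists = [
            np.linalg.norm((np.asarray(c) - np.asarray(seed_local)) * spacing)
            for c in centroids
        ]
        best = int(np.argmin(dists))
        if dists[best] > params.roi_half_width_mm:
            raise NoLesionFoundError(
                f"nearest candidate component is {dists[best]:.1f} mm from the "
                f"seed (> ROI half-width {params.roi_half_width_mm} mm)"
            )
        lab = best + 1
    comp = labels == lab
    comp = ndimage.binary_fill_holes(comp)
    for z in range(comp.shape[2]):  # slice-wise fill catches tunnels along z
        comp[:, :, z] = ndimage.binary_fill_holes(comp[:, :, z])
    comp = ndimage.binary_fill_holes(comp)

    mask = np.zeros(shape, dtype=bool)
    mask[roi] = comp
    return mask


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap coefficient between two boolean masks."""
    a, b = mask_a.astype(bool), mask_b.astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
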