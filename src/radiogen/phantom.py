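"""Synthetic DCE-MRI lesion phantoms.

Generates a dynamic contrast-enhanced series (one pre-contrast frame plus
several timed post-contrast frames) containing a single spiculated-sphere
lesion with a prescribed enhancement kinetic curve, together with its
ground-truth voxel mask.  The phantoms emulate a breast DCE-MRI protocol:
anisotropic voxels, 75 s frame spacing, and the three canonical kinetic
curve types (persistent, plateau, washout).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

KINETIC_TYPES = ("persistent", "plateau", "washout")

#: default frame times in seconds: one pre-contrast frame at t=0 and five
#: post-contrast frames at 75 s spacing
DEFAULT_FRAME_TIMES = (0.0, 75.0, 150.0, 225.0, 300.0, 375.0)

#: fraction of the peak lost by the last frame for washout curves
WASHOUT_LOSS = 0.30


@dataclass(frozen=True)
class DceMriSeries:
    """A DCE-MRI series: frames indexed (t, x, y, z) on a shared grid.

    Frame 0 is the pre-contrast acquisition; frames 1..T-1 are post-contrast.
    ``spacing`` is the voxel size in mm per axis, ``frame_times`` in seconds.
    """

    frames: np.ndarray
    spacing: tuple[float, float, float]
    frame_times: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.frames.ndim != 4:
            raise ValueError(f"frames must be 4D (t,x,y,z), got {self.frames.ndim}D")
        if len(self.frame_times) != self.frames.shape[0]:
            raise ValueError("frame_times length must match number of frames")
        times = np.asarray(self.frame_times)
        if times[0] != 0 or np.any(np.diff(times) <= 0):
            raise ValueError("frame_times must start at 0 and be strictly increasing")
        if self.frames.shape[0] < 3:
            raise ValueError("need one pre-contrast and at least 2 post-contrast frames")

    @property
    def n_post(self) -> int:
        return self.frames.shape[0] - 1

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.frames.shape[1:]

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, kinetics and noise model of a single-lesion phantom.

    Parameters
    ----------
    grid_shape : voxels per axis.
    voxel_spacing : mm per axis (anisotropic allowed).
    lesion_center : voxel coordinates of the lesion centre.
    lesion_radius : mean radius in mm.
    spiculation_amplitude : fractional radial perturbation (>= 0); 0 gives a
        sphere, larger values give increasingly spiculated margins.
    kinetic_type : "persistent", "plateau" or "washout".
    peak_enhancement : peak relative enhancement (fraction of baseline).
    heterogeneity_sd : SD of the per-voxel multiplicative enhancement factor
        (fraction of 1); models within-lesion heterogeneity.
    noise_sd : SD of additive acquisition noise as a fraction of baseline.
    frame_times : seconds; first must be 0 (pre-contrast).
    background_intensity : baseline signal in arbitrary units.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 64)
    voxel_spacing: tuple[float, float, float] = (0.76, 0.76, 1.6)
    lesion_center: tuple[float, float, float] | None = None
    lesion_radius: float = 8.0
    spiculation_amplitude: float = 0.0
    kinetic_type: str = "plateau"
    peak_enhancement: float = 1.0
    heterogeneity_sd: float = 0.0
    noise_sd: float = 0.0
    frame_times: tuple[float, ...] = DEFAULT_FRAME_TIMES
    background_intensity: float = 100.0

    def __post_init__(self) -> None:
        if self.kinetic_type not in KINETIC_TYPES:
            raise ValueError(
                f"kinetic_type must be one of {KINETIC_TYPES}, got {self.kinetic_type!r}"
            )
        times = np.asarray(self.frame_times, dtype=float)
        if times[0] != 0:
            raise ValueError("first frame time must be 0 (pre-contrast)")
        if np.any(np.diff(times) <= 0):
            raise ValueError("frame_times must be strictly increasing")
        if len(times) < 3:
            raise ValueError("need >= 2 post-contrast frames")
        if self.spiculation_amplitude < 0:
            raise ValueError("spiculation_amplitude must be >= 0")
        center = self.center_voxel
        for ax in range(3):
            # worst-case radius, in voxels, plus the required 2-voxel margin
            extent = self.lesion_radius * (1 + self.spiculation_amplitude)
            margin = extent / self.voxel_spacing[ax] + 2
            if center[ax] - margin < 0 or center[ax] + margin > self.grid_shape[ax] - 1:
                raise ValueError(
                    f"lesion (radius {self.lesion_radius} mm, spiculation "
                    f"{self.spiculation_amplitude}) does not fit inside the grid "
                    f"along axis {ax} with a 2-voxel margin"
                )

    @property
    def center_voxel(self) -> tuple[float, float, float]:
        if self.lesion_center is not None:
            return self.lesion_center
        return tuple((s - 1) / 2.0 for s in self.grid_shape)


def kinetic_curve(kinetic_type: str, times: np.ndarray) -> np.ndarray:
    """Normalized enhancement curve c(t) with peak value 1.

    persistent: saturating monotone rise reaching exactly 1 at the last frame;
    plateau: linear rise to 1 at the second post-contrast frame, then flat;
    washout: same rise, then linear decay losing ``WASHOUT_LOSS`` of the peak
    by the last frame.  c(0) = 0 for all types.
    """
    times = np.asarray(times, dtype=float)
    t_last = times[-1]
    if kinetic_type == "persistent":
        # normalized so that c(t_last) == 1 exactly
        c = (1 - np.exp(-3 * times / t_last)) / (1 - np.exp(-3.0))
        c[0] = 0.0
        return c
    # plateau / washout peak at the second post-contrast frame
    t_peak = times[2] if len(times) > 2 else times[-1]
    rise = np.minimum(times / t_peak, 1.0)
    if kinetic_type == "plateau":
        return rise
    if kinetic_type == "washout":
        decay = np.where(
            times > t_peak,
            1.0 - WASHOUT_LOSS * (times - t_peak) / (t_last - t_peak),
            1.0,
        )
        return np.where(times <= t_peak, rise, decay)
    raise ValueError(f"unknown kinetic_type {kinetic_type!r}")


def _radial_perturbation(directions: np.ndarray, rng: np.random.Generator,
                         n_waves: int = 6, max_freq: float = 5.0) -> np.ndarray:
    """Band-limited random perturbation P(direction) in [-1, 1].

    Sum of a few cosine waves of random spatial frequency/orientation
    evaluated on the unit sphere; normalized to unit maximum amplitude so
    that radii scale as r = R (1 + amplitude * P).
    """
    waves = rng.standard_normal((n_waves, 3))
    waves /= np.linalg.norm(waves, axis=1, keepdims=True)
    freqs = rng.uniform(2.0, max_freq, size=n_waves)
    phases = rng.uniform(0, 2 * np.pi, size=n_waves)
    amps = rng.uniform(0.5, 1.0, size=n_waves)
    proj = directions @ waves.T  # (n, n_waves)
    p = (amps * np.cos(freqs * np.pi * proj + phases)).sum(axis=1)
    peak = np.max(np.abs(p))
    if peak == 0:
        return p
    return p / peak


def lesion_mask_from_spec(spec: PhantomSpec, rng_seed: int) -> np.ndarray:
    """Ground-truth boolean mask of the (possibly spiculated) lesion."""
    shape = spec.grid_shape
    spacing = np.asarray(spec.voxel_spacing)
    center = np.asarray(spec.center_voxel)
    coords = np.stack(
        np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij"),
        axis=-1,
    )
    delta_mm = (coords - center) * spacing  # (x,y,z,3)
    dist = np.linalg.norm(delta_mm, axis=-1)
    if spec.spiculation_amplitude == 0:
        return dist <= spec.lesion_radius

    # evaluate the fixed band-limited perturbation only where it can matter
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([rng_seed, 7])))
    outer = spec.lesion_radius * (1 + spec.spiculation_amplitude)
    cand = dist <= outer
    with np.errstate(invalid="ignore"):
        dirs = delta_mm[cand] / dist[cand][..., None]
    dirs = np.nan_to_num(dirs)  # centre voxel direction is irrelevant (dist 0)
    p = _radial_perturbation(dirs, rng)
    radius_local = spec.lesion_radius * (1 + spec.spiculation_amplitude * p)
    mask = np.zeros(shape, dtype=bool)
    mask[cand] = dist[cand] <= radius_local
    return mask


def generate_lesion_phantom(
    spec: PhantomSpec, rng_seed: int
) -> tuple[DceMriSeries, np.ndarray]:
    """Generate a DCE-MRI series and its ground-truth lesion mask.

    The pre-contrast frame is ``background_intensity`` (plus noise)
    everywhere.  Lesion voxels follow the kinetic curve scaled by
    ``peak_enhancement`` with per-voxel multiplicative heterogeneity:

        S(x, t) = B * (1 + h(x) * peak_enhancement * c(t)) + noise

    where h(x) ~ N(1, heterogeneity_sd) truncated at 0.1.  The same seed
    yields bit-identical output.
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([rng_seed])))
    mask = lesion_mask_from_spec(spec, rng_seed)
    times = np.asarray(spec.frame_times, dtype=float)
    curve = kinetic_curve(spec.kinetic_type, times)
    bg = spec.background_intensity

    n_lesion = int(mask.sum())
    if spec.heterogeneity_sd > 0:
        het = rng.normal(1.0, spec.heterogeneity_sd, size=n_lesion)
        het = np.maximum(het, 0.1)
    else:
        het = np.ones(n_lesion)

    frames = np.empty((len(times),) + spec.grid_shape, dtype=np.float64)
    for t_idx, c in enumerate(curve):
        frame = np.full(spec.grid_shape, bg, dtype=np.float64)
        frame[mask] = bg * (1.0 + het * spec.peak_enhancement * c)
        if spec.noise_sd > 0:
            frame += rng.normal(0.0, spec.noise_sd * bg, size=spec.grid_shape)
        frames[t_idx] = frame

    series = DceMriSeries(
        frames=frames,
        spacing=tuple(spec.voxel_spacing),
        frame_times=tuple(times.tolist()),
    )
    return series, mask


# ---------------------------------------------------------------------------
# NIfTI I/O


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    return aff


def write_series(series: DceMriSeries, path: str | Path, seed: int | None = None) -> None:
    """Write the series as a single 4D NIfTI plus a JSON manifest."""
    path = Path(path)
    img = nib.Nifti1Image(np.moveaxis(series.frames, 0, -1), _affine(series.spacing))
    nib.save(img, path)
    manifest = {
        "frame_times_s": list(series.frame_times),
        "voxel_spacing_mm": list(series.spacing),
        "rng_seed": seed,
    }
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def read_series(path: str | Path) -> DceMriSeries:
    path = Path(path)
    img = nib.load(path)
    data = np.moveaxis(np.asarray(img.dataobj, dtype=np.float64), -1, 0)
    manifest_path = path.with_suffix("").with_suffix(".json")
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        times = tuple(manifest["frame_times_s"])
        spacing = tuple(manifest["voxel_spacing_mm"])
    else:
        spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
        times = tuple(75.0 * i for i in range(data.shape[0]))
    return DceMriSeries(frames=data, spacing=spacing, frame_times=times)


def write_mask(mask: np.ndarray, spacing: tuple[float, float, float],
               path: str | Path) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), _affine(spacing)), Path(path))


def read_mask(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(Path(path)).dataobj) > 0
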