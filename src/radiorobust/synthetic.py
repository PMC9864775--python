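"""Synthetic CT-like lesion phantoms with three segmentation styles.

Emulates a lung-CT lesion cohort: each "patient" is an ellipsoidal lesion with
spatially correlated texture and additive noise on an anisotropic grid, plus
three 3D segmentations of the same lesion —

* ``ACCURATE_FREEHAND``: the exact digitized ellipsoid,
* ``ROUGH_FREEHAND``: the lesion expanded by a margin with a smooth random
  radial perturbation of the boundary (a sloppy free-hand contour),
* ``ROUGH_POLYGON``: per-slice convex polygons circumscribing the expanded
  lesion cross-section (a coarse polygonal contour),

so the full robustness pipeline can run without any imaging data.  Rough
styles are supersets of the accurate mask by construction whenever the jitter
amplitude is below the margin.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .images import Mask, Volume, write_image


class SegmentationStyle(enum.Enum):
    ACCURATE_FREEHAND = "accurate_freehand"
    ROUGH_FREEHAND = "rough_freehand"
    ROUGH_POLYGON = "rough_polygon"


STYLES: tuple[SegmentationStyle, ...] = tuple(SegmentationStyle)

# Tangent polygon with >= 8 sides never extends beyond 1/cos(pi/8) times the
# circumscribed ellipse; used in grid-fit validation.
_POLYGON_SLACK = 1.0 / np.cos(np.pi / 8)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one lesion phantom.

    Intensities are HU-like: background near lung parenchyma, lesion near
    soft tissue.  ``texture_correlation_length`` is the Gaussian smoothing
    scale (mm) of the in-lesion texture field; ``texture_amplitude`` its
    standard deviation; ``noise_sd`` the i.i.d. noise SD everywhere.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 48)
    spacing: tuple[float, float, float] = (0.75, 0.75, 1.25)
    lesion_center: tuple[float, float, float] = (23.625, 23.625, 29.375)
    lesion_radii: tuple[float, float, float] = (9.0, 8.0, 7.0)
    lesion_mean_intensity: float = 40.0
    background_intensity: float = -800.0
    texture_amplitude: float = 40.0
    texture_correlation_length: float = 3.0
    background_texture_amplitude: float = 100.0
    noise_sd: float = 10.0
    seed: int = 0
    margin_mm: float = 2.0
    jitter_mm: float = 1.0
    polygon_vertex_range: tuple[int, int] = (8, 12)

    def __post_init__(self) -> None:
        if any(n < 8 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be >= 8 per axis, got {self.grid_shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if any(r <= 0 for r in self.lesion_radii):
            raise ValueError(f"lesion_radii must be positive, got {self.lesion_radii}")
        if self.noise_sd < 0 or self.texture_amplitude < 0:
            raise ValueError("noise_sd and texture_amplitude must be >= 0")
        for a in range(3):
            lo = self.lesion_center[a] - self.lesion_radii[a]
            hi = self.lesion_center[a] + self.lesion_radii[a]
            margin = 2 * self.spacing[a]
            extent = (self.grid_shape[a] - 1) * self.spacing[a]
            if lo < margin or hi > extent - margin:
                raise ValueError(
                    f"lesion extends to [{lo:.1f}, {hi:.1f}] mm on axis {a}, "
                    f"outside the grid interior [{margin:.1f}, {extent - margin:.1f}] mm"
                )

    def _coords(self) -> tuple[np.ndarray, ...]:
        """Per-axis world coordinates of voxel centers (origin at 0)."""
        return tuple(
            np.arange(self.grid_shape[a]) * self.spacing[a] for a in range(3)
        )

    def scaled_radius_sq(self) -> np.ndarray:
        """Sum of ((x_a - c_a)/r_a)^2 over the grid; lesion is where this <= 1."""
        x, y, z = self._coords()
        cx, cy, cz = self.lesion_center
        rx, ry, rz = self.lesion_radii
        return (
            ((x - cx) / rx)[:, None, None] ** 2
            + ((y - cy) / ry)[None, :, None] ** 2
            + ((z - cz) / rz)[None, None, :] ** 2
        )


def generate_phantom(spec: PhantomSpec) -> Volume:
    """Render the phantom volume: background + lesion + texture + noise.

    The texture field is white noise smoothed with a Gaussian of sigma equal
    to the correlation length (converted to voxels per axis), rescaled to unit
    SD over the grid, scaled by ``texture_amplitude`` and added inside the
    lesion only.  i.i.d. ``noise_sd`` noise is added everywhere.  Fully
    deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    inside = spec.scaled_radius_sq() <= 1.0
    vol = np.full(spec.grid_shape, spec.background_intensity, dtype=np.float64)
    vol[inside] = spec.lesion_mean_intensity

    sigma_vox = [spec.texture_correlation_length / s for s in spec.spacing]

    def correlated_field(amplitude: float) -> np.ndarray:
        white = rng.standard_normal(spec.grid_shape)
        field = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="reflect")
        sd = field.std()
        return field * (amplitude / sd) if sd > 0 else field

    lesion_texture = correlated_field(spec.texture_amplitude)
    # parenchyma-like structure (vessels, septa) surrounding the lesion: a
    # patient-specific field, so rough masks pick up idiosyncratic tissue
    background_texture = correlated_field(spec.background_texture_amplitude)
    if spec.texture_amplitude > 0:
        vol[inside] += lesion_texture[inside]
    if spec.background_texture_amplitude > 0:
        vol[~inside] += background_texture[~inside]

    noise = rng.standard_normal(spec.grid_shape)
    if spec.noise_sd > 0:
        vol += spec.noise_sd * noise
    return Volume(vol, spec.spacing)


def _direction_field(spec: PhantomSpec, rng: np.random.Generator, n_bumps: int = 12) -> np.ndarray:
    """Smooth random scalar field of the radial direction, max |value| = 1.

    A sum of Gaussian bumps centred at random points on the unit sphere gives
    a band-limited perturbation resembling free-hand contour wobble.
    """
    x, y, z = spec._coords()
    rel = np.stack(
        [
            (x - spec.lesion_center[0])[:, None, None] * np.ones(spec.grid_shape),
            (y - spec.lesion_center[1])[None, :, None] * np.ones(spec.grid_shape),
            (z - spec.lesion_center[2])[None, None, :] * np.ones(spec.grid_shape),
        ],
        axis=-1,
    )
    norm = np.linalg.norm(rel, axis=-1, keepdims=True)
    u = np.divide(rel, norm, out=np.zeros_like(rel), where=norm > 0)

    centers = rng.standard_normal((n_bumps, 3))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    amps = rng.standard_normal(n_bumps)
    f = np.zeros(spec.grid_shape)
    for a, c in zip(amps, centers):
        d2 = ((u - c) ** 2).sum(axis=-1)
        f += a * np.exp(-d2 / (2 * 0.5**2))
    f -= f.mean()
    peak = np.abs(f).max()
    if peak > 0:
        f /= peak
    return f


def _check_fits(spec: PhantomSpec, extra_mm: float, what: str) -> None:
    for a in range(3):
        r = spec.lesion_radii[a] + extra_mm
        extent = (spec.grid_shape[a] - 1) * spec.spacing[a]
        if spec.lesion_center[a] - r < 0 or spec.lesion_center[a] + r > extent:
            raise ValueError(
                f"{what}: margin pushes the mask outside the grid on axis {a} "
                f"(needs radius {r:.1f} mm at center {spec.lesion_center[a]:.1f} mm)"
            )


def generate_segmentation(
    spec: PhantomSpec, style: SegmentationStyle, seed: int
) -> Mask:
    """Digitize one of the three segmentation styles for the phantom lesion."""
    rng = np.random.default_rng(seed)

    if style is SegmentationStyle.ACCURATE_FREEHAND:
        fg = spec.scaled_radius_sq() <= 1.0
    elif style is SegmentationStyle.ROUGH_FREEHAND:
        _check_fits(spec, spec.margin_mm + spec.jitter_mm, "rough freehand")
        jitter = spec.jitter_mm * _direction_field(spec, rng)
        x, y, z = spec._coords()
        cx, cy, cz = spec.lesion_center
        rx, ry, rz = spec.lesion_radii
        m = spec.margin_mm
        s2 = (
            ((x - cx)[:, None, None] / (rx + m + jitter)) ** 2
            + ((y - cy)[None, :, None] / (ry + m + jitter)) ** 2
            + ((z - cz)[None, None, :] / (rz + m + jitter)) ** 2
        )
        fg = s2 <= 1.0
    elif style is SegmentationStyle.ROUGH_POLYGON:
        _check_fits(spec, spec.margin_mm * _POLYGON_SLACK + max(spec.lesion_radii) * (_POLYGON_SLACK - 1), "rough polygon")
        fg = _polygon_mask(spec, rng)
    else:  # pragma: no cover
        raise ValueError(f"unknown style {style}")

    if not fg.any():
        raise ValueError(f"{style.value} digitized to an empty mask")
    return Mask(fg.astype(np.uint8), spec.spacing, style=style.value)


def _polygon_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-slice convex tangent polygons around the margin-expanded lesion.

    Each occupied slice gets an n-gon whose sides are tangent to the
    margin-expanded elliptical cross-section, so the polygon circumscribes
    (contains) the accurate cross-section on every slice.
    """
    lo, hi = spec.polygon_vertex_range
    n_vertices = int(rng.integers(lo, hi + 1))
    base_angles = 2 * np.pi * np.arange(n_vertices) / n_vertices
    phase = rng.uniform(0, 2 * np.pi)

    x, y, z = spec._coords()
    cx, cy, cz = spec.lesion_center
    rx, ry, rz = spec.lesion_radii
    m = spec.margin_mm
    fg = np.zeros(spec.grid_shape, dtype=bool)
    xx = (x - cx)[:, None]
    yy = (y - cy)[None, :]
    for k in range(spec.grid_shape[2]):
        dz = (z[k] - cz) / (rz + m)
        if abs(dz) >= 1.0:
            continue
        scale = np.sqrt(1.0 - dz**2)
        a, b = (rx + m) * scale, (ry + m) * scale
        # small per-slice rotation jitter keeps contours hand-drawn-looking
        angles = base_angles + phase + rng.uniform(-0.15, 0.15, n_vertices)
        inside = np.ones((spec.grid_shape[0], spec.grid_shape[1]), dtype=bool)
        for t in angles:
            # tangent line to the ellipse at parameter t: x cos t / a + y sin t / b = 1
            inside &= (xx * np.cos(t) / a + yy * np.sin(t) / b) <= 1.0
        fg[:, :, k] = inside
    return fg


# ---------------------------------------------------------------------------
# Cohort generation


@dataclass(frozen=True)
class CohortConfig:
    """Ranges from which per-patient phantom parameters are drawn.

    The rough-segmentation margin scales with lesion size (``margin_frac`` of
    the geometric-mean radius, floored at ``margin_floor_mm``), emulating
    radiologists whose "rough" over-segmentation is a thin rim relative to
    the tumour rather than a fixed absolute band; jitter is half the margin
    so rough masks stay supersets of the accurate mask.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 48)
    spacing: tuple[float, float, float] = (0.75, 0.75, 1.25)
    radius_range_mm: tuple[float, float] = (4.0, 15.0)
    center_jitter_mm: float = 3.0
    lesion_intensity_range: tuple[float, float] = (20.0, 80.0)
    background_intensity: float = -800.0
    texture_amplitude_range: tuple[float, float] = (20.0, 60.0)
    texture_correlation_length: float = 3.0
    background_texture_range: tuple[float, float] = (50.0, 150.0)
    noise_sd_range: tuple[float, float] = (5.0, 15.0)
    margin_frac: float = 0.08
    margin_floor_mm: float = 0.3


@dataclass(frozen=True)
class PatientPhantom:
    patient_id: str
    spec: PhantomSpec
    volume: Volume
    masks: dict[SegmentationStyle, Mask] = field(repr=False)


def sample_spec(config: CohortConfig, rng: np.random.Generator, seed: int) -> PhantomSpec:
    # log-uniform radii: tumour size distributions are right-skewed
    lo, hi = config.radius_range_mm
    radii = tuple(np.exp(rng.uniform(np.log(lo), np.log(hi), size=3)))
    grid_center = tuple(
        (n - 1) * s / 2 for n, s in zip(config.grid_shape, config.spacing)
    )
    center = tuple(
        c + rng.uniform(-config.center_jitter_mm, config.center_jitter_mm)
        for c in grid_center
    )
    margin = max(config.margin_floor_mm, config.margin_frac * float(np.cbrt(np.prod(radii))))
    return PhantomSpec(
        grid_shape=config.grid_shape,
        spacing=config.spacing,
        lesion_center=center,
        lesion_radii=radii,
        lesion_mean_intensity=rng.uniform(*config.lesion_intensity_range),
        background_intensity=config.background_intensity,
        texture_amplitude=rng.uniform(*config.texture_amplitude_range),
        texture_correlation_length=config.texture_correlation_length,
        background_texture_amplitude=rng.uniform(*config.background_texture_range),
        noise_sd=rng.uniform(*config.noise_sd_range),
        seed=int(rng.integers(0, 2**31 - 1)),
        margin_mm=margin,
        jitter_mm=margin / 2.0,
    )


def generate_cohort(
    n_patients: int = 48,
    master_seed: int = 0,
    config: CohortConfig | None = None,
) -> list[PatientPhantom]:
    """Generate ``n_patients`` phantoms, each with three segmentations.

    Per-patient sub-seeds derive from ``master_seed`` only, so the cohort is a
    pure function of ``(n_patients, master_seed, config)`` and each patient is
    reproducible independently of the others.
    """
    if n_patients < 2:
        raise ValueError("need n_patients >= 2")
    config = config or CohortConfig()
    master = np.random.default_rng(master_seed)
    patient_seeds = master.integers(0, 2**31 - 1, size=n_patients)

    cohort: list[PatientPhantom] = []
    for p, pseed in enumerate(patient_seeds):
        rng = np.random.default_rng(pseed)
        spec = sample_spec(config, rng, seed=int(pseed))
        style_seeds = rng.integers(0, 2**31 - 1, size=len(STYLES))
        volume = generate_phantom(spec)
        masks = {
            style: generate_segmentation(spec, style, int(s))
            for style, s in zip(STYLES, style_seeds)
        }
        cohort.append(PatientPhantom(f"P{p:03d}", spec, volume, masks))
    return cohort


def write_cohort(
    cohort: list[PatientPhantom], directory: str | Path, fmt: str = "nii.gz"
) -> Path:
    """Write one volume + three mask files per patient plus a manifest CSV."""
    if fmt not in ("nii.gz", "nii", "nrrd"):
        raise ValueError(f"unsupported format {fmt!r}")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for pat in cohort:
        vol_path = directory / f"{pat.patient_id}_volume.{fmt}"
        write_image(pat.volume, vol_path)
        row: dict[str, object] = {
            "patient_id": pat.patient_id,
            "volume_path": vol_path.name,
            "seed": pat.spec.seed,
            "radius_x_mm": pat.spec.lesion_radii[0],
            "radius_y_mm": pat.spec.lesion_radii[1],
            "radius_z_mm": pat.spec.lesion_radii[2],
        }
        for style in STYLES:
            mpath = directory / f"{pat.patient_id}_mask_{style.value}.{fmt}"
            write_image(pat.masks[style], mpath)
            row[f"mask_{style.value}"] = mpath.name
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(directory / "manifest.csv", index=False)
    return directory
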