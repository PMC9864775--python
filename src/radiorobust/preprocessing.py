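"""Preprocessing axes of the extraction grid.

Three operations, corresponding to the tunable parameters whose effect on
feature robustness is under study:

* :func:`resample` — volume + mask to an isotropic grid with a chosen
  intensity interpolator (masks always nearest-neighbour);
* :func:`discretize` — fixed-bin-width gray-level discretization of the
  in-mask intensities (IBSI "fixed bin size", anchored at the in-mask
  minimum);
* :func:`wavelet_decompose` — single-level undecimated separable 3D coiflet-1
  decomposition into the 8 low/high sub-bands (LLL … HHH).
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass

import numpy as np
import pywt
import SimpleITK as sitk
from scipy import ndimage

from .images import Mask, Volume, mask_from_sitk, to_sitk, volume_from_sitk


class Interpolator(enum.Enum):
    NEAREST = "nearest"
    LINEAR = "linear"
    SPLINE = "spline"  # cubic B-spline, order 3


_SITK_INTERP = {
    Interpolator.NEAREST: sitk.sitkNearestNeighbor,
    Interpolator.LINEAR: sitk.sitkLinear,
    Interpolator.SPLINE: sitk.sitkBSpline,
}

#: sub-band labels; letter ``a`` of three refers to array axis ``a``
WAVELET_SUBBANDS: tuple[str, ...] = tuple(
    "".join(c) for c in itertools.product("LH", repeat=3)
)  # LLL, LLH, LHL, LHH, HLL, HLH, HHL, HHH — L first so the approximation leads

IMAGE_FILTERS: tuple[str, ...] = ("original",) + tuple(
    f"wavelet-{b}" for b in WAVELET_SUBBANDS
)


@dataclass(frozen=True)
class ExtractionConfig:
    """One point of the preprocessing parameter grid."""

    bin_width: float = 20.0
    pixel_distance: int = 1
    interpolator: Interpolator = Interpolator.LINEAR
    resolution_mm: float = 2.0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if self.pixel_distance < 1:
            raise ValueError("pixel_distance must be >= 1")
        if self.resolution_mm <= 0:
            raise ValueError("resolution_mm must be > 0")
        if not isinstance(self.interpolator, Interpolator):
            object.__setattr__(self, "interpolator", Interpolator(self.interpolator))

    @property
    def config_id(self) -> str:
        return (
            f"bw{self.bin_width:g}_d{self.pixel_distance}"
            f"_{self.interpolator.value}_r{self.resolution_mm:g}mm"
        )


#: the study's default full factorial grid
DEFAULT_GRID = {
    "bin_width": (10.0, 20.0, 40.0),
    "pixel_distance": (1, 2, 4),
    "interpolator": (Interpolator.NEAREST, Interpolator.LINEAR, Interpolator.SPLINE),
    "resolution_mm": (1.0, 2.0, 2.5),
}


def make_grid(
    bin_width=DEFAULT_GRID["bin_width"],
    pixel_distance=DEFAULT_GRID["pixel_distance"],
    interpolator=DEFAULT_GRID["interpolator"],
    resolution_mm=DEFAULT_GRID["resolution_mm"],
) -> list[ExtractionConfig]:
    """Full factorial grid over the four preprocessing parameters."""
    interps = [Interpolator(i) for i in interpolator]
    return [
        ExtractionConfig(bw, int(d), it, r)
        for bw, d, it, r in itertools.product(bin_width, pixel_distance, interps, resolution_mm)
    ]


def resample(
    volume: Volume,
    mask: Mask,
    resolution_mm: float,
    interpolator: Interpolator | str = Interpolator.LINEAR,
) -> tuple[Volume, Mask]:
    """Resample volume + mask to an isotropic grid of ``resolution_mm``.

    Intensities use the requested interpolator; the mask is always resampled
    nearest-neighbour and stays binary.  The output grid keeps the input
    origin and covers the input world extent (sizes rounded up).
    """
    if resolution_mm <= 0:
        raise ValueError("resolution must be > 0")
    interpolator = Interpolator(interpolator)
    mask.check_aligned(volume)

    new_spacing = (resolution_mm,) * 3
    new_size = tuple(
        max(1, int(np.ceil(n * s / resolution_mm)))
        for n, s in zip(volume.shape, volume.spacing)
    )

    def _run(img: sitk.Image, interp, default: float) -> sitk.Image:
        rs = sitk.ResampleImageFilter()
        rs.SetOutputSpacing(new_spacing)
        rs.SetSize(tuple(int(n) for n in new_size))
        rs.SetOutputOrigin(img.GetOrigin())
        rs.SetOutputDirection(img.GetDirection())
        rs.SetInterpolator(interp)
        rs.SetDefaultPixelValue(default)
        return rs.Execute(img)

    # out-of-domain voxels: background intensity for the image, 0 for the mask
    vol_img = _run(to_sitk(volume), _SITK_INTERP[interpolator], float(np.min(volume.voxels)))
    mask_img = _run(to_sitk(mask), sitk.sitkNearestNeighbor, 0.0)
    new_vol = volume_from_sitk(vol_img)
    new_mask = mask_from_sitk(mask_img, style=mask.style)
    if new_mask.n_voxels == 0:  # pragma: no cover — Mask raises first
        raise ValueError("resampled mask is empty (degenerate ROI)")
    return new_vol, new_mask


@dataclass(frozen=True)
class DiscretizedRegion:
    """Gray levels 1..Ng over the in-mask voxels of a volume.

    ``grid`` is the full-shape integer array with 0 outside the mask, which
    texture-matrix construction needs for neighbourhood lookups; ``levels``
    is the flat in-mask level vector.
    """

    grid: np.ndarray
    mask: np.ndarray
    ng: int
    bin_width: float
    spacing: tuple[float, float, float]

    @property
    def levels(self) -> np.ndarray:
        return self.grid[self.mask]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def discretize(volume: Volume, mask: Mask, bin_width: float) -> DiscretizedRegion:
    """IBSI fixed-bin-size rule: level = floor((x - min_in_mask)/W) + 1."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    mask.check_aligned(volume)
    m = mask.voxels
    vals = volume.voxels[m]
    lev = np.floor((vals - vals.min()) / bin_width).astype(np.int64) + 1
    grid = np.zeros(volume.shape, dtype=np.int64)
    grid[m] = lev
    return DiscretizedRegion(
        grid=grid, mask=m, ng=int(lev.max()), bin_width=float(bin_width),
        spacing=volume.spacing,
    )


def _coif1_filters() -> tuple[np.ndarray, np.ndarray]:
    w = pywt.Wavelet("coif1")
    return np.asarray(w.dec_lo), np.asarray(w.dec_hi)


def wavelet_decompose(volume: Volume) -> dict[str, Volume]:
    """Undecimated single-level 3D coiflet-1 decomposition.

    The low/high decomposition filters are applied separably along each axis
    in all 2^3 combinations, with symmetric (mirror) boundary handling and no
    downsampling, so every sub-band keeps the input shape and spacing and
    region masks apply unchanged.
    """
    lo, hi = _coif1_filters()
    flen = len(lo)
    if any(n < flen for n in volume.shape):
        raise ValueError(
            f"each axis must be >= the filter length {flen}, got {volume.shape}"
        )
    bands: dict[str, Volume] = {}
    for label in WAVELET_SUBBANDS:
        arr = volume.voxels
        for axis, letter in enumerate(label):
            kernel = lo if letter == "L" else hi
            arr = ndimage.convolve1d(arr, kernel, axis=axis, mode="reflect")
        bands[label] = Volume(arr, volume.spacing, volume.origin)
    return bands
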