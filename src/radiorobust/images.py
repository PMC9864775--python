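"""Grid-aligned 3D image containers and file I/O.

A :class:`Volume` is a scalar 3D array with per-axis voxel spacing (mm) and a
world origin; a :class:`Mask` is a binary region on the same grid.  Arrays are
indexed ``(i, j, k)`` with ``spacing[a]`` the physical step along array axis
``a``; the last axis is conventionally the slice (through-plane) axis.  File
I/O (NIfTI, NRRD) goes through SimpleITK, which uses the reversed (x, y, z)
axis order — the converters below handle the flip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk
from scipy import ndimage


@dataclass(frozen=True)
class Volume:
    """3D scalar image with anisotropic voxel spacing and world origin."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=np.float64)
        if vox.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={vox.ndim}")
        if not np.all(np.isfinite(vox)):
            raise ValueError("volume contains non-finite values")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_centers(self, mask: np.ndarray | None = None) -> np.ndarray:
        """World coordinates (mm) of voxel centers, optionally restricted to a mask."""
        if mask is None:
            idx = np.indices(self.shape).reshape(3, -1).T
        else:
            idx = np.argwhere(mask)
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)


@dataclass(frozen=True)
class Mask:
    """Binary 3D region aligned to a :class:`Volume`."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    style: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={vox.ndim}")
        if not np.isin(np.unique(vox), (0, 1)).all():
            raise ValueError("mask must be binary (0/1)")
        vox = vox.astype(bool)
        if vox.sum() < 1:
            raise ValueError("mask has no foreground voxels")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def is_connected(self) -> bool:
        """True if the foreground is a single 26-connected component."""
        _, n = ndimage.label(self.voxels, structure=np.ones((3, 3, 3), dtype=bool))
        return n == 1

    def check_aligned(self, volume: Volume) -> None:
        if self.shape != volume.shape:
            raise ValueError(f"mask shape {self.shape} != volume shape {volume.shape}")
        if not np.allclose(self.spacing, volume.spacing):
            raise ValueError(f"mask spacing {self.spacing} != volume spacing {volume.spacing}")
        if not np.allclose(self.origin, volume.origin, atol=1e-6):
            raise ValueError(f"mask origin {self.origin} != volume origin {volume.origin}")


# ---------------------------------------------------------------------------
# SimpleITK conversion and file I/O


def to_sitk(obj: Volume | Mask) -> sitk.Image:
    arr = obj.voxels
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    # sitk.GetImageFromArray treats axis 0 as z: our axis order is preserved
    # by reversing spacing/origin so that world coordinates agree.
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(arr, (2, 1, 0))))
    img.SetSpacing(tuple(obj.spacing))
    img.SetOrigin(tuple(obj.origin))
    return img


def volume_from_sitk(img: sitk.Image) -> Volume:
    arr = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    return Volume(arr.astype(np.float64), tuple(img.GetSpacing()), tuple(img.GetOrigin()))


def mask_from_sitk(img: sitk.Image, style: str | None = None) -> Mask:
    arr = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    return Mask((arr > 0).astype(np.uint8), tuple(img.GetSpacing()), tuple(img.GetOrigin()), style=style)


def write_image(obj: Volume | Mask, path: str | Path) -> None:
    """Write a volume or mask to NIfTI (.nii/.nii.gz) or NRRD (.nrrd)."""
    sitk.WriteImage(to_sitk(obj), str(path), useCompression=True)


def read_volume(path: str | Path) -> Volume:
    return volume_from_sitk(sitk.ReadImage(str(path)))


def read_mask(path: str | Path, style: str | None = None) -> Mask:
    return mask_from_sitk(sitk.ReadImage(str(path)), style=style)
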