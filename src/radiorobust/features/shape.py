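"""3D shape features of a binary mask (intensity-independent).

Mesh quantities (volume, surface area and derived ratios) come from a
marching-cubes triangulation of the binary mask at level 0.5; axis lengths
come from the eigenvalues of the covariance of in-mask voxel-center physical
coordinates, reported as 4*sqrt(lambda) (the full axis length of an
equivalent uniform ellipsoid's bounding description used throughout the
radiomics literature).  Diameters are maximal pairwise distances between
boundary voxel centers, overall (3D) and per orthogonal plane family (2D).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from skimage.measure import marching_cubes, mesh_surface_area

from ..images import Mask

SHAPE_NAMES = (
    "MeshVolume",
    "VoxelVolume",
    "SurfaceArea",
    "SurfaceVolumeRatio",
    "Sphericity",
    "Maximum3DDiameter",
    "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn",
    "Maximum2DDiameterRow",
    "MajorAxisLength",
    "MinorAxisLength",
    "LeastAxisLength",
    "Elongation",
    "Flatness",
)


def _mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    """Signed tetrahedron sum (divergence theorem) over the closed surface."""
    tri = verts[faces]
    signed = np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2]))
    return abs(signed.sum()) / 6.0


def _max_pairwise(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    if len(points) > 100:
        try:  # the diameter is attained on the convex hull
            points = points[ConvexHull(points).vertices]
        except QhullError:
            pass  # degenerate (coplanar) cloud: brute-force below
    return float(pdist(points).max())


def _max_2d_diameter(coords: np.ndarray, along_axis: int) -> float:
    """Max in-plane pairwise distance within any slice orthogonal to an axis."""
    in_plane = [a for a in range(3) if a != along_axis]
    best = 0.0
    for v in np.unique(coords[:, along_axis]):
        pts = coords[coords[:, along_axis] == v][:, in_plane]
        best = max(best, _max_pairwise(pts))
    return best


def shape_features(mask: Mask) -> dict[str, float]:
    """Compute the 14 shape descriptors of a mask.

    A single-voxel mask has no surface mesh; its mesh-derived values are NaN
    and its axis lengths collapse to 0 with Elongation = Flatness = 1.
    """
    m = mask.voxels
    spacing = np.asarray(mask.spacing)
    n = mask.n_voxels
    out: dict[str, float] = dict.fromkeys(SHAPE_NAMES, np.nan)
    out["VoxelVolume"] = n * float(np.prod(spacing))

    coords = np.argwhere(m) * spacing  # physical voxel centers
    centered = coords - coords.mean(axis=0)
    eig = np.sort(np.linalg.eigvalsh(centered.T @ centered / n))[::-1]
    eig = np.clip(eig, 0.0, None)
    out["MajorAxisLength"] = 4.0 * np.sqrt(eig[0])
    out["MinorAxisLength"] = 4.0 * np.sqrt(eig[1])
    out["LeastAxisLength"] = 4.0 * np.sqrt(eig[2])
    if eig[0] > 0:
        out["Elongation"] = float(np.sqrt(eig[1] / eig[0]))
        out["Flatness"] = float(np.sqrt(eig[2] / eig[0]))
    else:
        out["Elongation"] = out["Flatness"] = 1.0

    if n < 2:
        return out

    # slight pre-smoothing suppresses the stair-step area inflation of a
    # binary marching-cubes surface while barely moving the 0.5 level set
    padded = np.pad(m, 2).astype(np.float64)
    smoothed = ndimage.gaussian_filter(padded, sigma=0.5)
    if smoothed.max() <= 0.5:  # tiny mask: smoothing erased the level set
        smoothed = padded
    verts, faces, _, _ = marching_cubes(smoothed, level=0.5, spacing=tuple(spacing))
    mesh_vol = _mesh_volume(verts, faces)
    area = float(mesh_surface_area(verts, faces))
    out["MeshVolume"] = mesh_vol
    out["SurfaceArea"] = area
    out["SurfaceVolumeRatio"] = area / mesh_vol
    out["Sphericity"] = float((36.0 * np.pi * mesh_vol**2) ** (1.0 / 3.0) / area)

    boundary = m & ~ndimage.binary_erosion(m)
    bcoords = np.argwhere(boundary) * spacing
    out["Maximum3DDiameter"] = _max_pairwise(bcoords)
    # plane families: Slice = through-plane axis 2, Column = axis 1, Row = axis 0
    out["Maximum2DDiameterSlice"] = _max_2d_diameter(bcoords, along_axis=2)
    out["Maximum2DDiameterColumn"] = _max_2d_diameter(bcoords, along_axis=1)
    out["Maximum2DDiameterRow"] = _max_2d_diameter(bcoords, along_axis=0)
    return out
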