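"""Five gray-level texture-matrix families: GLCM, GLRLM, GLSZM, NGTDM, GLDM.

All families operate on a :class:`~radiorobust.preprocessing.DiscretizedRegion`
(levels 1..Ng, 0 outside the mask).  Directional families (GLCM, GLRLM) build
one matrix per unique 3D direction — 13 of the 26 neighbour offsets, one per
antipodal pair — compute each feature per direction and average over
directions.  Neighbourhood families (NGTDM, GLDM) use the full Chebyshev
ball of radius ``distance``; GLCM offsets are ``distance`` times the unit
direction in voxel index space.

Degenerate-input conventions (documented constants, so every feature stays
numeric for downstream agreement statistics): on a single-level region GLCM
Correlation, Imc1, Imc2 and MCC are 1 (perfect-dependence limit); NGTDM
Coarseness is capped at 1e6 when its denominator vanishes; Busyness and
Strength are 0 when theirs do.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import ndimage

from ..preprocessing import DiscretizedRegion

#: 13 unique (lexicographically positive) directions among the 26 neighbours
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    d
    for d in itertools.product((-1, 0, 1), repeat=3)
    if d > (0, 0, 0)
)

COARSENESS_CAP = 1e6

GLCM_NAMES = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares", "MCC",
)
GLRLM_NAMES = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)
GLSZM_NAMES = (
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)
NGTDM_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")
GLDM_NAMES = (
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)


def _cropped(disc: DiscretizedRegion) -> np.ndarray:
    """Level grid cropped to the mask bounding box (0 outside the mask)."""
    idx = np.argwhere(disc.mask)
    lo, hi = idx.min(axis=0), idx.max(axis=0) + 1
    return disc.grid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]


def _pair_slices(shape, offset):
    """Slices (a, b) such that arr[a] and arr[b] are voxel pairs at `offset`."""
    src, dst = [], []
    for n, o in zip(shape, offset):
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    return tuple(src), tuple(dst)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


# ---------------------------------------------------------------------------
# GLCM


def glcm_matrices(
    disc: DiscretizedRegion, distance: int
) -> dict[tuple[int, int, int], np.ndarray]:
    """Symmetric co-occurrence count matrices keyed by direction.

    Entry ``[i-1, j-1]`` counts ordered pairs of levels (i, j) at offset
    ``distance * direction`` plus its reverse (symmetrization).  Directions
    with no in-mask pairs are omitted.
    """
    grid = _cropped(disc)
    ng = disc.ng
    mats: dict[tuple[int, int, int], np.ndarray] = {}
    for d in DIRECTIONS_13:
        off = tuple(distance * c for c in d)
        if any(abs(o) >= n for o, n in zip(off, grid.shape)):
            continue
        a, b = _pair_slices(grid.shape, off)
        la, lb = grid[a].ravel(), grid[b].ravel()
        keep = (la > 0) & (lb > 0)
        if not keep.any():
            continue
        la, lb = la[keep] - 1, lb[keep] - 1
        c = np.bincount(la * ng + lb, minlength=ng * ng).reshape(ng, ng).astype(float)
        mats[d] = c + c.T
    return mats


def _glcm_from_matrix(c: np.ndarray, ng_hint: int) -> dict[str, float]:
    p = c / c.sum()
    px_full = p.sum(axis=1)
    occ = px_full > 0
    iv = np.flatnonzero(occ) + 1.0  # actual gray-level values
    p = p[np.ix_(occ, occ)]
    px = p.sum(axis=1)  # == py by symmetry
    ngo = len(iv)
    mu = float((iv * px).sum())
    sigma2 = float(((iv - mu) ** 2 * px).sum())
    I, J = np.meshgrid(iv, iv, indexing="ij")

    sum_p = np.bincount((I + J).astype(int).ravel(), weights=p.ravel())
    diff_idx = np.abs(I - J).astype(int)
    diff_p = np.bincount(diff_idx.ravel(), weights=p.ravel())
    kdiff = np.arange(len(diff_p))
    da = float((kdiff * diff_p).sum())

    autoc = float((I * J * p).sum())
    contrast = float(((I - J) ** 2 * p).sum())
    hx = _entropy(px)
    hxy = _entropy(p.ravel())
    pxpy = np.outer(px, px)
    pos = p > 0
    hxy1 = float(-(p[pos] * np.log2(pxpy[pos])).sum())
    hxy2 = _entropy(pxpy.ravel())

    if ngo == 1:
        corr = imc1 = imc2 = mcc = 1.0
    else:
        corr = (autoc - mu * mu) / sigma2 if sigma2 > 0 else 1.0
        imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0  # hx == hy by symmetry
        imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
        q = p @ (p / np.outer(px, px))  # Q[i,j] = sum_k p[i,k] p[j,k] / (px[i] px[k])
        eig = np.sort(np.linalg.eigvals(q).real)
        mcc = float(np.sqrt(max(0.0, eig[-2]))) if len(eig) > 1 else 1.0

    absdiff = np.abs(I - J)
    offdiag = absdiff > 0
    return {
        "Autocorrelation": autoc,
        "JointAverage": mu,
        "ClusterProminence": float(((I + J - 2 * mu) ** 4 * p).sum()),
        "ClusterShade": float(((I + J - 2 * mu) ** 3 * p).sum()),
        "ClusterTendency": float(((I + J - 2 * mu) ** 2 * p).sum()),
        "Contrast": contrast,
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": _entropy(diff_p),
        "DifferenceVariance": float(((kdiff - da) ** 2 * diff_p).sum()),
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "Imc1": imc1,
        "Imc2": imc2,
        "Idm": float((p / (1.0 + (I - J) ** 2)).sum()),
        "Idmn": float((p / (1.0 + ((I - J) / ngo) ** 2)).sum()),
        "Id": float((p / (1.0 + absdiff)).sum()),
        "Idn": float((p / (1.0 + absdiff / ngo)).sum()),
        "InverseVariance": float((p[offdiag] / (I - J)[offdiag] ** 2).sum()),
        "MaximumProbability": float(p.max()),
        "SumAverage": float(((I + J) * p).sum()),
        "SumEntropy": _entropy(sum_p),
        "SumSquares": float(((I - mu) ** 2 * p).sum()),
        "MCC": mcc,
    }


def glcm_features(disc: DiscretizedRegion, distance: int) -> dict[str, float]:
    """24 co-occurrence features, averaged over the 13 directions."""
    mats = list(glcm_matrices(disc, distance).values())
    if not mats:  # single-voxel region: treat as a one-cell constant matrix
        mats = [np.array([[1.0]])]
    per_dir = [_glcm_from_matrix(c, disc.ng) for c in mats]
    return {k: float(np.mean([d[k] for d in per_dir])) for k in GLCM_NAMES}


# ---------------------------------------------------------------------------
# GLRLM


def glrlm_matrices(disc: DiscretizedRegion) -> list[np.ndarray]:
    """Run-length count matrices ``[level-1, length-1]``, one per direction.

    Voxels are grouped into lattice lines per direction by an integer line
    id, sorted by position along the line, and run boundaries found where
    the line, the position step, or the level changes (out-of-mask voxels
    break runs because they are simply absent from the sorted list).
    """
    coords = np.argwhere(disc.mask)
    levels = disc.grid[disc.mask]
    mats = []
    for d in DIRECTIONS_13:
        dv = np.asarray(d)
        step = int(dv @ dv)
        t = coords @ dv
        line_id = coords * step - t[:, None] * dv  # constant along each line
        order = np.lexsort((t, line_id[:, 2], line_id[:, 1], line_id[:, 0]))
        ts, ls, lid = t[order], levels[order], line_id[order]
        new_run = np.ones(len(ts), dtype=bool)
        if len(ts) > 1:
            same_line = (lid[1:] == lid[:-1]).all(axis=1)
            contiguous = np.diff(ts) == step
            same_level = ls[1:] == ls[:-1]
            new_run[1:] = ~(same_line & contiguous & same_level)
        starts = np.flatnonzero(new_run)
        lengths = np.diff(np.append(starts, len(ts)))
        run_levels = ls[starts]
        m = np.zeros((disc.ng, lengths.max()), dtype=float)
        np.add.at(m, (run_levels - 1, lengths - 1), 1.0)
        mats.append(m)
    return mats


def _weighted_var(p: np.ndarray, w: np.ndarray) -> float:
    mu = float((w * p).sum())
    return float(((w - mu) ** 2 * p).sum())


def _rlm_szm_features(m: np.ndarray, n_voxels: int, names) -> dict[str, float]:
    """Shared GLRLM/GLSZM feature formulas (second index = run length / zone size)."""
    ns = m.sum()
    iv = np.arange(1, m.shape[0] + 1, dtype=float)
    jv = np.arange(1, m.shape[1] + 1, dtype=float)
    gi = m.sum(axis=1)  # per gray level
    sj = m.sum(axis=0)  # per length/size
    p = m / ns
    I, J = np.meshgrid(iv, jv, indexing="ij")
    vals = (
        float((sj / jv**2).sum() / ns),
        float((sj * jv**2).sum() / ns),
        float((gi**2).sum() / ns),
        float((gi**2).sum() / ns**2),
        float((sj**2).sum() / ns),
        float((sj**2).sum() / ns**2),
        float(ns / n_voxels),
        _weighted_var(gi / ns, iv),
        _weighted_var(sj / ns, jv),
        _entropy(p.ravel()),
        float((gi / iv**2).sum() / ns),
        float((gi * iv**2).sum() / ns),
        float((p / (I**2 * J**2)).sum()),
        float((p * I**2 / J**2).sum()),
        float((p * J**2 / I**2).sum()),
        float((p * I**2 * J**2).sum()),
    )
    return dict(zip(names, vals))


def glrlm_features(disc: DiscretizedRegion) -> dict[str, float]:
    """16 run-length features, averaged over the 13 directions."""
    per_dir = [
        _rlm_szm_features(m, disc.n_voxels, GLRLM_NAMES)
        for m in glrlm_matrices(disc)
    ]
    return {k: float(np.mean([d[k] for d in per_dir])) for k in GLRLM_NAMES}


# ---------------------------------------------------------------------------
# GLSZM


def glszm_matrix(disc: DiscretizedRegion) -> np.ndarray:
    """Zone count matrix ``[level-1, size-1]`` from 26-connected components."""
    grid = _cropped(disc)
    structure = np.ones((3, 3, 3), dtype=bool)
    zones: list[tuple[int, int]] = []
    for g in np.unique(grid[grid > 0]):
        lab, nlab = ndimage.label(grid == g, structure=structure)
        sizes = np.bincount(lab.ravel())[1:]
        zones.extend((int(g), int(s)) for s in sizes)
    smax = max(s for _, s in zones)
    m = np.zeros((disc.ng, smax), dtype=float)
    for g, s in zones:
        m[g - 1, s - 1] += 1.0
    return m


def glszm_features(disc: DiscretizedRegion) -> dict[str, float]:
    """16 size-zone features (direction-free)."""
    return _rlm_szm_features(glszm_matrix(disc), disc.n_voxels, GLSZM_NAMES)


# ---------------------------------------------------------------------------
# NGTDM


def _box_sum(arr: np.ndarray, distance: int) -> np.ndarray:
    size = 2 * distance + 1
    return ndimage.uniform_filter(arr, size=size, mode="constant", cval=0.0) * size**3


def ngtdm_matrix(disc: DiscretizedRegion, distance: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-level ``(s_i, n_i)``: coarse-difference sums and voxel counts.

    ``s_i`` sums |level - mean of in-mask neighbours within the Chebyshev
    ball| over in-mask voxels of level i; voxels with no in-mask neighbour
    are excluded from both.
    """
    grid = _cropped(disc)
    inmask = (grid > 0).astype(np.float64)
    nb_count = np.rint(_box_sum(inmask, distance)) - inmask
    nb_sum = _box_sum(grid.astype(np.float64), distance) - grid
    valid = (grid > 0) & (nb_count > 0)
    diffs = np.abs(grid[valid] - nb_sum[valid] / nb_count[valid])
    lev = grid[valid]
    s = np.zeros(disc.ng)
    np.add.at(s, lev - 1, diffs)
    n = np.bincount(lev - 1, minlength=disc.ng).astype(float)
    return s, n


def ngtdm_features(disc: DiscretizedRegion, distance: int) -> dict[str, float]:
    """Coarseness, Contrast, Busyness, Complexity, Strength."""
    s, n = ngtdm_matrix(disc, distance)
    nvp = n.sum()
    if nvp == 0:  # isolated voxels only: no valid neighbourhoods
        return {"Coarseness": COARSENESS_CAP, "Contrast": 0.0, "Busyness": 0.0,
                "Complexity": 0.0, "Strength": 0.0}
    p = n / nvp
    iv = np.arange(1, disc.ng + 1, dtype=float)
    occ = p > 0
    ngp = int(occ.sum())
    po, so, io = p[occ], s[occ], iv[occ]

    denom = float((p * s).sum())
    coarseness = 1.0 / denom if denom > 0 else COARSENESS_CAP
    coarseness = min(coarseness, COARSENESS_CAP)

    if ngp > 1:
        ii, jj = np.meshgrid(io, io, indexing="ij")
        ppi, ppj = np.meshgrid(po, po, indexing="ij")
        ssi, ssj = np.meshgrid(so, so, indexing="ij")
        contrast = float((ppi * ppj * (ii - jj) ** 2).sum()) / (ngp * (ngp - 1)) * s.sum() / nvp
        busy_den = float(np.abs(ii * ppi - jj * ppj).sum())
        busyness = denom / busy_den if busy_den > 0 else 0.0
        complexity = float((np.abs(ii - jj) * (ppi * ssi + ppj * ssj) / (ppi + ppj)).sum()) / nvp
        strength = float(((ppi + ppj) * (ii - jj) ** 2).sum()) / s.sum() if s.sum() > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0
    return {"Coarseness": coarseness, "Contrast": contrast, "Busyness": busyness,
            "Complexity": complexity, "Strength": strength}


# ---------------------------------------------------------------------------
# GLDM


def gldm_matrix(disc: DiscretizedRegion, distance: int, alpha: int = 0) -> np.ndarray:
    """Dependence count matrix ``[level-1, j-1]``.

    A neighbour (Chebyshev ball of radius ``distance``) is dependent when its
    level differs by at most ``alpha``; the second index is the dependence
    count plus one (the centre voxel depends on itself), so j >= 1 always.
    """
    grid = _cropped(disc)
    jmax = (2 * distance + 1) ** 3
    m = np.zeros((disc.ng, jmax), dtype=float)
    if alpha == 0:
        for g in np.unique(grid[grid > 0]):
            eq = (grid == g).astype(np.float64)
            j = np.rint(_box_sum(eq, distance)[grid == g]).astype(int)
            np.add.at(m, (g - 1, j - 1), 1.0)
    else:  # generic alpha: per-level band counting
        for g in np.unique(grid[grid > 0]):
            band = ((np.abs(grid - g) <= alpha) & (grid > 0)).astype(np.float64)
            j = np.rint(_box_sum(band, distance)[grid == g]).astype(int)
            np.add.at(m, (g - 1, j - 1), 1.0)
    return m[:, : int(np.flatnonzero(m.sum(axis=0)).max()) + 1]


def gldm_features(disc: DiscretizedRegion, distance: int) -> dict[str, float]:
    """14 gray-level dependence features."""
    m = gldm_matrix(disc, distance)
    nz = m.sum()
    iv = np.arange(1, m.shape[0] + 1, dtype=float)
    jv = np.arange(1, m.shape[1] + 1, dtype=float)
    gi = m.sum(axis=1)
    dj = m.sum(axis=0)
    p = m / nz
    I, J = np.meshgrid(iv, jv, indexing="ij")
    return dict(zip(GLDM_NAMES, (
        float((dj / jv**2).sum() / nz),
        float((dj * jv**2).sum() / nz),
        float((gi**2).sum() / nz),
        float((dj**2).sum() / nz),
        float((dj**2).sum() / nz**2),
        _weighted_var(gi / nz, iv),
        _weighted_var(dj / nz, jv),
        _entropy(p.ravel()),
        float((gi / iv**2).sum() / nz),
        float((gi * iv**2).sum() / nz),
        float((p / (I**2 * J**2)).sum()),
        float((p * I**2 / J**2).sum()),
        float((p * J**2 / I**2).sum()),
        float((p * I**2 * J**2).sum()),
    )))
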