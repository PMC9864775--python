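"""Independent brute-force reference implementations for the test suite.

Everything here enumerates voxel pairs / runs / zones / neighbourhoods with
plain Python loops and sets, sharing no code with the production modules, so
any disagreement flags a real defect in one of the two.  Inputs are small
integer level grids (0 = outside the mask), at most ~10^3 voxels.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats as sps

# the 13 antipodal-unique 3D directions, written out literally
BRUTE_DIRECTIONS = [
    (0, 0, 1),
    (0, 1, -1), (0, 1, 0), (0, 1, 1),
    (1, -1, -1), (1, -1, 0), (1, -1, 1),
    (1, 0, -1), (1, 0, 0), (1, 0, 1),
    (1, 1, -1), (1, 1, 0), (1, 1, 1),
]


def _check_size(grid: np.ndarray) -> None:
    if grid.size > 1000:
        raise ValueError("oracle refuses regions larger than 10^3 voxels")


def _in(grid: np.ndarray, v: tuple[int, int, int]) -> bool:
    return all(0 <= c < n for c, n in zip(v, grid.shape)) and grid[v] > 0


def brute_glcm(grid: np.ndarray, distance: int) -> dict[tuple, np.ndarray]:
    """Symmetrized co-occurrence counts per direction (ordered both ways)."""
    _check_size(grid)
    ng = int(grid.max())
    out: dict[tuple, np.ndarray] = {}
    for d in BRUTE_DIRECTIONS:
        m = np.zeros((ng, ng))
        npairs = 0
        for v in itertools.product(*(range(n) for n in grid.shape)):
            if grid[v] == 0:
                continue
            for sign in (+1, -1):
                w = tuple(c + sign * distance * o for c, o in zip(v, d))
                if _in(grid, w):
                    m[grid[v] - 1, grid[w] - 1] += 1
                    npairs += 1
        if npairs:
            out[d] = m
    return out


def brute_glrlm(grid: np.ndarray) -> list[np.ndarray]:
    """Run-length counts [level-1, length-1] per direction, by walking runs."""
    _check_size(grid)
    ng = int(grid.max())
    mats = []
    for d in BRUTE_DIRECTIONS:
        runs: list[tuple[int, int]] = []
        for v in itertools.product(*(range(n) for n in grid.shape)):
            if grid[v] == 0:
                continue
            prev = tuple(c - o for c, o in zip(v, d))
            if _in(grid, prev) and grid[prev] == grid[v]:
                continue  # not a run start
            length = 1
            w = tuple(c + o for c, o in zip(v, d))
            while _in(grid, w) and grid[w] == grid[v]:
                length += 1
                w = tuple(c + o for c, o in zip(w, d))
            runs.append((int(grid[v]), length))
        lmax = max(l for _, l in runs)
        m = np.zeros((ng, lmax))
        for g, l in runs:
            m[g - 1, l - 1] += 1
        mats.append(m)
    return mats


def brute_glszm(grid: np.ndarray) -> np.ndarray:
    """Zone counts [level-1, size-1] by breadth-first flood fill (26-conn)."""
    _check_size(grid)
    ng = int(grid.max())
    seen: set[tuple] = set()
    zones: list[tuple[int, int]] = []
    offsets = [o for o in itertools.product((-1, 0, 1), repeat=3) if o != (0, 0, 0)]
    for v in itertools.product(*(range(n) for n in grid.shape)):
        if grid[v] == 0 or v in seen:
            continue
        frontier, zone = [v], {v}
        while frontier:
            u = frontier.pop()
            for o in offsets:
                w = tuple(c + oc for c, oc in zip(u, o))
                if w not in zone and _in(grid, w) and grid[w] == grid[v]:
                    zone.add(w)
                    frontier.append(w)
        seen |= zone
        zones.append((int(grid[v]), len(zone)))
    smax = max(s for _, s in zones)
    m = np.zeros((ng, smax))
    for g, s in zones:
        m[g - 1, s - 1] += 1
    return m


def _chebyshev_ball(distance: int):
    return [
        o
        for o in itertools.product(range(-distance, distance + 1), repeat=3)
        if o != (0, 0, 0)
    ]


def brute_ngtdm(grid: np.ndarray, distance: int) -> tuple[np.ndarray, np.ndarray]:
    """(s_i, n_i): |level - mean of in-mask neighbours| sums and counts."""
    _check_size(grid)
    ng = int(grid.max())
    s = np.zeros(ng)
    n = np.zeros(ng)
    ball = _chebyshev_ball(distance)
    for v in itertools.product(*(range(m) for m in grid.shape)):
        if grid[v] == 0:
            continue
        nb = [
            grid[w]
            for o in ball
            if _in(grid, w := tuple(c + oc for c, oc in zip(v, o)))
        ]
        if not nb:
            continue
        i = int(grid[v])
        n[i - 1] += 1
        s[i - 1] += abs(i - sum(nb) / len(nb))
    return s, n


def brute_gldm(grid: np.ndarray, distance: int, alpha: int = 0) -> np.ndarray:
    """Dependence counts [level-1, j-1], j = dependent neighbours + 1."""
    _check_size(grid)
    ng = int(grid.max())
    ball = _chebyshev_ball(distance)
    counts: list[tuple[int, int]] = []
    for v in itertools.product(*(range(m) for m in grid.shape)):
        if grid[v] == 0:
            continue
        j = 1  # the centre depends on itself
        for o in ball:
            w = tuple(c + oc for c, oc in zip(v, o))
            if _in(grid, w) and abs(int(grid[w]) - int(grid[v])) <= alpha:
                j += 1
        counts.append((int(grid[v]), j))
    jmax = max(j for _, j in counts)
    m = np.zeros((ng, jmax))
    for g, j in counts:
        m[g - 1, j - 1] += 1
    return m


# ---------------------------------------------------------------------------
# ICC oracle: explicit double-loop ANOVA, McGraw & Wong (A,1) construction


def brute_icc(x: np.ndarray, alpha: float = 0.05):
    """(icc, ci_lower, ci_upper, msr, msc, mse) from first principles."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = 0.0
    for i in range(n):
        for j in range(k):
            grand += x[i, j]
    grand /= n * k
    row = [sum(x[i, j] for j in range(k)) / k for i in range(n)]
    col = [sum(x[i, j] for i in range(n)) / n for j in range(k)]
    ss_r = k * sum((r - grand) ** 2 for r in row)
    ss_c = n * sum((c - grand) ** 2 for c in col)
    ss_e = 0.0
    for i in range(n):
        for j in range(k):
            ss_e += (x[i, j] - row[i] - col[j] + grand) ** 2
    msr = ss_r / (n - 1)
    msc = ss_c / (k - 1)
    mse = ss_e / ((n - 1) * (k - 1))

    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    if mse == 0 and msc == 0:
        return 1.0, 1.0, 1.0, msr, msc, mse
    a = k * icc / (n * (1 - icc))
    b = 1 + k * icc * (n - 1) / (n * (1 - icc))
    if mse > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
    else:
        v = k - 1
    fl = sps.f.ppf(1 - alpha / 2, n - 1, v)
    fu = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - fl * mse) / (fl * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (fu * msr - mse) / (k * msc + (k * n - k - n) * mse + n * fu * msr)
    return icc, min(lower, icc), max(min(upper, 1.0), icc), msr, msc, mse


def brute_spearman(x, y) -> float:
    """Spearman rho via explicit mid-ranking and Pearson on ranks."""

    def midrank(v):
        v = list(v)
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r = (i + j) / 2 + 1
            for t in range(i, j + 1):
                ranks[order[t]] = r
            i = j + 1
        return ranks

    rx, ry = midrank(x), midrank(y)
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    ) ** 0.5
    return num / den
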