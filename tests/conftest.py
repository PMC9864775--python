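import numpy as np
import pytest

from radiorobust.preprocessing import DiscretizedRegion
from radiorobust.synthetic import PhantomSpec


def make_disc(levels: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> DiscretizedRegion:
    """DiscretizedRegion from a literal integer grid (0 = outside mask)."""
    grid = np.asarray(levels, dtype=np.int64)
    if grid.ndim == 2:
        grid = grid[..., None]
    assert grid.ndim == 3
    return DiscretizedRegion(
        grid=grid,
        mask=grid > 0,
        ng=int(grid.max()),
        bin_width=1.0,
        spacing=tuple(spacing),
    )


def random_level_grid(rng: np.random.Generator, max_side=6, max_level=4) -> np.ndarray:
    """Random small level grid with a random mask; min occupied level is 1."""
    shape = tuple(rng.integers(2, max_side + 1, size=3))
    grid = rng.integers(1, max_level + 1, size=shape)
    mask = rng.random(shape) < 0.7
    if not mask.any():
        mask.flat[0] = True
    grid[~mask] = 0
    occ = grid > 0
    grid[occ] -= grid[occ].min() - 1  # anchor lowest occupied level at 1
    return grid


@pytest.fixture
def small_spec() -> PhantomSpec:
    """Desk-scale phantom: coarse grid, modest lesion, full anisotropy."""
    return PhantomSpec(
        grid_shape=(32, 32, 24),
        spacing=(1.5, 1.5, 2.5),
        lesion_center=(23.25, 23.25, 28.75),
        lesion_radii=(8.0, 7.0, 6.5),
        seed=7,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
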