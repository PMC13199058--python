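import numpy as np
import pytest

from recurmap.volumes_io import GridSpec, LabelVolume


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_mask(grid: GridSpec, coords) -> LabelVolume:
    data = np.zeros(grid.shape, dtype=bool)
    for c in coords:
        data[tuple(c)] = True
    return LabelVolume.from_mask(data, grid, name="mask")


def random_blob(grid: GridSpec, rng: np.random.Generator, n_seeds: int = 4,
                radius_vox: float = 3.0) -> LabelVolume:
    """A random union of small balls, guaranteed non-empty."""
    shape = np.asarray(grid.shape)
    data = np.zeros(grid.shape, dtype=bool)
    idx = np.indices(grid.shape).reshape(3, -1).T
    for _ in range(n_seeds):
        center = rng.uniform(0.2, 0.8, size=3) * (shape - 1)
        r = rng.uniform(1.0, radius_vox)
        data |= (((idx - center) ** 2).sum(axis=1) <= r * r).reshape(grid.shape)
    if not data.any():
        data[tuple(shape // 2)] = True
    return LabelVolume.from_mask(data, grid, name="mask")


@pytest.fixture
def small_grid():
    return GridSpec.isotropic(20, 1.0)
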