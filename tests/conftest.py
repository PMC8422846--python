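import numpy as np
import pytest

from btiradiomics.grids import MaskVolume, VoxelGrid


def sphere(shape, spacing, center_mm, radius_mm):
    coords = np.meshgrid(
        *[np.arange(s) * d for s, d in zip(shape, spacing)], indexing="ij"
    )
    d2 = sum((c - cc) ** 2 for c, cc in zip(coords, center_mm))
    return d2 <= radius_mm**2


@pytest.fixture(scope="session")
def unit_sphere_grid():
    """Digital sphere r=10 mm at 1 mm isotropic spacing, centered off-lattice."""
    shape, sp = (44, 44, 44), (1.0, 1.0, 1.0)
    rng = np.random.default_rng(7)
    grid = VoxelGrid(rng.normal(100.0, 10.0, shape), sp)
    tumor = MaskVolume(sphere(shape, sp, (21.5, 21.5, 21.5), 10.0), grid)
    return grid, tumor


@pytest.fixture(scope="session")
def small_cohort():
    """A 24-subject phantom cohort on small grids, shared across tests."""
    from btiradiomics.synthetic_cohort import PhantomConfig, generate_cohort

    cfg = PhantomConfig(
        grid_shape=(32, 32, 32),
        spacing_mm=(2.0, 2.0, 2.0),
        tumor_radius_range_mm=(6.0, 10.0),
        edema_volume_params={"noninvasive": (2.0, 0.7), "invasive": (6.0, 0.6)},
        n_subjects=24,
        seed=11,
    )
    return cfg, generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
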