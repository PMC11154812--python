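import numpy as np
import pytest

from hemilat.core_io import BoldSeries, partition_hemispheres
from hemilat.synthetic_cohort import default_grid, default_mask


@pytest.fixture(scope="session")
def small_geometry():
    """A symmetric 6x5x4 grid (even x-dim: no midline), ~90% masked."""
    grid = default_grid((6, 5, 4), 4.0)
    rng = np.random.default_rng(7)
    mask = rng.random((6, 5, 4)) < 0.9
    # keep the mask mirror-symmetric so every voxel has a defined mirror
    mask = mask | mask[::-1]
    return partition_hemispheres(grid, mask)


@pytest.fixture(scope="session")
def full_geometry():
    """Fully masked symmetric 6x5x4 grid."""
    grid = default_grid((6, 5, 4), 4.0)
    return partition_hemispheres(grid, np.ones((6, 5, 4), dtype=bool))


def make_series(geometry, data, tr_s=2.0, subject_id="sub"):
    data = np.asarray(data, dtype=float)
    return BoldSeries(
        subject_id=subject_id,
        geometry=geometry,
        data=data,
        tr_s=tr_s,
        kept_frames=np.arange(data.shape[0]),
    )


@pytest.fixture(scope="session")
def mirrored_series(full_geometry):
    """Random data duplicated across mirror pairs (left copied to right)."""
    rng = np.random.default_rng(3)
    geom = full_geometry
    data = rng.standard_normal((80, geom.n_voxels))
    left = np.flatnonzero((geom.side == 0) & (geom.mirror_index >= 0))
    data[:, geom.mirror_index[left]] = data[:, left]
    return make_series(geom, data)
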