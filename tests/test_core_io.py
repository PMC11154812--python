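import nibabel as nib
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemilat.core_io import (
    GeometryError,
    InsufficientDataError,
    LEFT,
    MIDLINE,
    MetricMap,
    RIGHT,
    VolumeGrid,
    load_bold_series,
    load_metric_map,
    partition_hemispheres,
    save_metric_map,
)
from hemilat.synthetic_cohort import default_grid

from conftest import make_series


def _write_nifti(path, data, affine, tr=2.0):
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    if data.ndim == 4:
        zooms = list(img.header.get_zooms())
        zooms[3] = tr
        img.header.set_zooms(zooms)
    nib.save(img, str(path))


class TestVolumeGrid:
    def test_voxel_size_equals_affine_column_norms(self):
        grid = default_grid((4, 4, 4), 3.0)
        assert np.allclose(grid.voxel_size_mm, 3.0, atol=1e-6)

    def test_singular_affine_rejected(self):
        aff = np.eye(4)
        aff[0, 0] = 0.0
        with pytest.raises(GeometryError):
            VolumeGrid(dims=(4, 4, 4), affine=aff)

    def test_nonpositive_dims_rejected(self):
        with pytest.raises(GeometryError):
            VolumeGrid(dims=(4, 0, 4), affine=np.eye(4))

    def test_mm_round_trip(self):
        grid = default_grid((5, 6, 7), 2.5)
        ijk = np.array([[1, 2, 3], [0, 0, 0], [4, 5, 6]])
        assert np.allclose(grid.mm_to_voxel(grid.voxel_to_mm(ijk)), ijk)


class TestPartitionHemispheres:
    def test_symmetric_full_mask_has_equal_hemispheres(self):
        grid = default_grid((4, 4, 4), 4.0)
        geom = partition_hemispheres(grid, np.ones((4, 4, 4), dtype=bool))
        assert geom.hi_left == geom.hi_right == 32
        assert not np.any(geom.side == MIDLINE)

    def test_odd_x_dim_central_plane_is_midline(self):
        grid = default_grid((5, 4, 4), 4.0)
        geom = partition_hemispheres(grid, np.ones((5, 4, 4), dtype=bool))
        mid = geom.side == MIDLINE
        assert mid.sum() == 16
        assert np.all(geom.voxel_ijk[mid, 0] == 2)
        assert geom.hi_left + geom.hi_right + mid.sum() == geom.n_voxels

    def test_asymmetric_mask_counts_and_involution(self):
        grid = default_grid((6, 5, 4), 4.0)
        mask = np.ones((6, 5, 4), dtype=bool)
        mask[4:, :, :] = False  # remove most of the right hemisphere
        geom = partition_hemispheres(grid, mask)
        assert geom.hi_left > geom.hi_right
        defined = geom.mirror_index >= 0
        # exhaustive involution check over all defined voxels
        assert np.all(
            geom.mirror_index[geom.mirror_index[defined]]
            == np.flatnonzero(defined)
        )
        # a mirrored voxel really sits at the negated x coordinate
        mm = geom.mm_coords
        pair_mm = mm[geom.mirror_index[defined]]
        assert np.allclose(pair_mm[:, 0], -mm[defined, 0])
        assert np.allclose(pair_mm[:, 1:], mm[defined, 1:])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_mirror_involution_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        grid = default_grid((6, 4, 4), 5.0)
        mask = rng.random((6, 4, 4)) < 0.7
        if not mask.any():
            mask[0, 0, 0] = True
        geom = partition_hemispheres(grid, mask)
        defined = geom.mirror_index >= 0
        assert np.all(
            geom.mirror_index[geom.mirror_index[defined]]
            == np.flatnonzero(defined)
        )
        half = grid.voxel_size_mm[0] / 2
        x = geom.mm_coords[:, 0]
        assert np.array_equal(geom.side == MIDLINE, np.abs(x) < half - 1e-9)
        assert (
            geom.hi_left + geom.hi_right + int((geom.side == MIDLINE).sum())
            == geom.n_voxels
        )


class TestLoadBoldSeries:
    def _setup(self, tmp_path, n_vol=30, dims=(4, 4, 3)):
        grid = default_grid(dims, 3.0)
        rng = np.random.default_rng(0)
        data4d = rng.standard_normal((*dims, n_vol))
        mask = rng.random(dims) < 0.8
        _write_nifti(tmp_path / "bold.nii.gz", data4d, grid.affine)
        _write_nifti(tmp_path / "mask.nii.gz", mask.astype(float), grid.affine)
        return data4d, mask

    def test_initial_volume_discard(self, tmp_path):
        self._setup(tmp_path, n_vol=30)
        s = load_bold_series(tmp_path / "bold.nii.gz", tmp_path / "mask.nii.gz", 10)
        assert s.n_frames == 20
        assert s.kept_frames[0] == 10

    def test_drop_zero_is_identity(self, tmp_path):
        data4d, mask = self._setup(tmp_path, n_vol=20)
        s = load_bold_series(tmp_path / "bold.nii.gz", tmp_path / "mask.nii.gz", 0)
        assert s.n_frames == 20

    def test_column_order_is_row_major_in_mask(self, tmp_path):
        data4d, mask = self._setup(tmp_path, n_vol=20)
        s = load_bold_series(tmp_path / "bold.nii.gz", tmp_path / "mask.nii.gz", 0)
        # brute-force voxel-by-voxel extraction in row-major order
        cols = []
        nx, ny, nz = mask.shape
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    if mask[i, j, k]:
                        cols.append(data4d[i, j, k, :])
        expected = np.array(cols).T
        assert s.data.shape == expected.shape
        assert np.array_equal(s.data, expected)

    def test_grid_mismatch_raises(self, tmp_path):
        self._setup(tmp_path)
        other = default_grid((4, 4, 3), 5.0)
        _write_nifti(tmp_path / "bad_mask.nii.gz", np.ones((4, 4, 3)), other.affine)
        with pytest.raises(GeometryError):
            load_bold_series(tmp_path / "bold.nii.gz", tmp_path / "bad_mask.nii.gz", 0)

    def test_too_few_frames_raises(self, tmp_path):
        self._setup(tmp_path, n_vol=15)
        with pytest.raises(InsufficientDataError):
            load_bold_series(tmp_path / "bold.nii.gz", tmp_path / "mask.nii.gz", 10)


class TestMetricMapIO:
    def test_round_trip_preserves_values_and_affine(self, small_geometry, tmp_path):
        rng = np.random.default_rng(1)
        m = MetricMap(small_geometry, rng.uniform(-1, 1, small_geometry.n_voxels), "AI")
        save_metric_map(m, tmp_path / "ai.nii.gz")
        loaded = load_metric_map(tmp_path / "ai.nii.gz", small_geometry, "AI")
        assert np.allclose(loaded.values, m.values, rtol=1e-6)
        img = nib.load(str(tmp_path / "ai.nii.gz"))
        assert np.array_equal(img.affine, small_geometry.grid.affine)

    def test_all_zero_map(self, small_geometry, tmp_path):
        m = MetricMap(small_geometry, np.zeros(small_geometry.n_voxels), "CFH")
        save_metric_map(m, tmp_path / "z.nii.gz")
        loaded = load_metric_map(tmp_path / "z.nii.gz", small_geometry, "CFH")
        assert np.all(loaded.values == 0)

    def test_single_voxel_lands_at_its_mm_coordinate(self, tmp_path):
        grid = default_grid((10, 10, 10), 2.0)
        geom = partition_hemispheres(grid, np.ones((10, 10, 10), dtype=bool))
        values = np.zeros(geom.n_voxels)
        v = 321
        values[v] = 0.5
        save_metric_map(MetricMap(geom, values, "AI"), tmp_path / "one.nii.gz")
        img = nib.load(str(tmp_path / "one.nii.gz"))
        vol = np.asarray(img.dataobj)
        ijk = np.argwhere(vol != 0)
        assert len(ijk) == 1
        mm_from_file = img.affine[:3, :3] @ ijk[0] + img.affine[:3, 3]
        assert np.allclose(mm_from_file, geom.mm_coords[v])

    def test_kind_range_validation(self, small_geometry):
        bad = np.full(small_geometry.n_voxels, 1.5)
        with pytest.raises(ValueError):
            MetricMap(small_geometry, bad, "AI")


def test_bold_series_rejects_short_series(full_geometry):
    with pytest.raises(InsufficientDataError):
        make_series(full_geometry, np.zeros((5, full_geometry.n_voxels)))


def test_swap_hemispheres_exchanges_labels_and_counts(small_geometry):
    sw = small_geometry.swap_hemispheres()
    assert sw.hi_left == small_geometry.hi_right
    assert sw.hi_right == small_geometry.hi_left
    assert np.array_equal(sw.side == LEFT, small_geometry.side == RIGHT)
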