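import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hemilat.core_io import MetricMap, partition_hemispheres
from hemilat.group_inference import (
    GroupDesign,
    cluster_fwe_permutation,
    extract_cluster_mean,
    extract_sphere_mean,
    partial_correlation,
    smooth_map,
    voxelwise_two_sample_t,
)
from hemilat.synthetic_cohort import default_grid


def _geom(dims=(8, 8, 6), vx=3.0, full=True, seed=0):
    grid = default_grid(dims, vx)
    if full:
        mask = np.ones(dims, dtype=bool)
    else:
        mask = np.random.default_rng(seed).random(dims) < 0.85
    return partition_hemispheres(grid, mask)


def _random_maps(geom, n, seed=0, kind="TSTAT"):
    rng = np.random.default_rng(seed)
    return [MetricMap(geom, rng.standard_normal(geom.n_voxels), kind) for _ in range(n)]


def _design(n1, n2):
    labels = np.array(["AD"] * n1 + ["HC"] * n2, dtype=object)
    return GroupDesign([f"s{i}" for i in range(n1 + n2)], labels)


class TestSmoothing:
    def test_constant_map_unchanged(self):
        geom = _geom(full=False)
        m = MetricMap(geom, np.full(geom.n_voxels, 0.4), "CFH")
        out = smooth_map(m, 8.0)
        assert np.allclose(out.values, 0.4, atol=1e-9)

    def test_zero_fwhm_is_identity(self):
        geom = _geom()
        rng = np.random.default_rng(1)
        m = MetricMap(geom, rng.standard_normal(geom.n_voxels), "TSTAT")
        assert np.array_equal(smooth_map(m, 0.0).values, m.values)

    def test_delta_profile_matches_analytic_gaussian(self):
        geom = _geom(dims=(21, 21, 21), vx=2.0)
        values = np.zeros(geom.n_voxels)
        center = np.flatnonzero(
            (geom.voxel_ijk == [10, 10, 10]).all(axis=1)
        )[0]
        values[center] = 1.0
        fwhm = 6.0
        out = smooth_map(MetricMap(geom, values, "TSTAT"), fwhm)
        sigma = fwhm / 2.3548200450309493
        # compare the ratio profile along +y against the closed form
        for offset_vox in (1, 2, 3):
            probe = np.flatnonzero(
                (geom.voxel_ijk == [10, 10 + offset_vox, 10]).all(axis=1)
            )[0]
            expected = np.exp(-0.5 * (offset_vox * 2.0 / sigma) ** 2)
            got = out.values[probe] / out.values[center]
            assert got == pytest.approx(expected, rel=0.01)

    def test_nan_voxels_stay_nan_and_do_not_bleed(self):
        geom = _geom()
        values = np.ones(geom.n_voxels)
        values[5] = np.nan
        out = smooth_map(MetricMap(geom, values, "TSTAT"), 6.0)
        assert np.isnan(out.values[5])
        finite = out.values[np.isfinite(out.values)]
        assert np.allclose(finite, 1.0, atol=1e-9)  # renormalized around the hole


class TestTwoSampleT:
    def test_identical_groups_give_zero(self):
        geom = _geom()
        maps = _random_maps(geom, 3, seed=2)
        all_maps = maps + [MetricMap(geom, m.values.copy(), "TSTAT") for m in maps]
        t = voxelwise_two_sample_t(all_maps, _design(3, 3))
        assert np.allclose(t.values, 0.0, atol=1e-12)

    def test_hand_computed_pooled_variance_example(self):
        geom = _geom(dims=(2, 1, 1))
        vals = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        maps = [MetricMap(geom, np.full(geom.n_voxels, v), "TSTAT") for v in vals]
        t = voxelwise_two_sample_t(maps, _design(3, 3))
        # pooled sd 1, se = sqrt(2/3): t = (2-5)/0.8165 = -3.674
        assert np.allclose(t.values, -3.0 / np.sqrt(2.0 / 3.0), atol=1e-12)

    def test_matches_scipy_oracle(self):
        geom = _geom()
        maps = _random_maps(geom, 14, seed=3)
        t = voxelwise_two_sample_t(maps, _design(6, 8))
        y = np.vstack([m.values for m in maps])
        ref = stats.ttest_ind(y[:6], y[6:], axis=0, equal_var=True).statistic
        assert np.allclose(t.values, ref, atol=1e-10)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            _design(1, 5)


class TestClusterPermutation:
    def test_same_seed_reproduces_table(self):
        geom = _geom()
        rng = np.random.default_rng(4)
        maps = []
        for i in range(16):
            v = rng.standard_normal(geom.n_voxels)
            if i < 8:
                v[:30] += 2.5  # group effect over a compact storage block
            maps.append(smooth_map(MetricMap(geom, v, "TSTAT"), 5.0))
        design = _design(8, 8)
        a = cluster_fwe_permutation(maps, design, voxel_p=1e-3, n_perm=200, seed=9)
        b = cluster_fwe_permutation(maps, design, voxel_p=1e-3, n_perm=200, seed=9)
        pd.testing.assert_frame_equal(a.clusters, b.clusters)
        assert np.array_equal(a.null_max_extent, b.null_max_extent)

    def test_group_label_swap_leaves_corrected_p_invariant(self):
        geom = _geom()
        rng = np.random.default_rng(5)
        maps = []
        for i in range(12):
            v = rng.standard_normal(geom.n_voxels)
            if i < 6:
                v[40:70] += 2.0
            maps.append(smooth_map(MetricMap(geom, v, "TSTAT"), 5.0))
        ids = [f"s{i}" for i in range(12)]
        lab = np.array(["AD"] * 6 + ["HC"] * 6, dtype=object)
        res1 = cluster_fwe_permutation(
            maps, GroupDesign(ids, lab), voxel_p=1e-3, n_perm=150, seed=3
        )
        swapped = np.where(lab == "AD", "HC", "AD").astype(object)
        res2 = cluster_fwe_permutation(
            maps, GroupDesign(ids, swapped), voxel_p=1e-3, n_perm=150, seed=3
        )
        # signs flip, extents and corrected p values agree
        assert np.allclose(
            np.sort(res1.clusters["p_corrected"]), np.sort(res2.clusters["p_corrected"])
        )
        assert sorted(res1.clusters["extent_voxels"]) == sorted(
            res2.clusters["extent_voxels"]
        )

    def test_small_cohorts_enumerate_all_relabelings(self):
        geom = _geom(dims=(6, 6, 4))
        maps = _random_maps(geom, 8, seed=6)
        res = cluster_fwe_permutation(
            maps, _design(4, 4), voxel_p=0.01, n_perm=1000, seed=0
        )
        from math import comb

        assert res.n_perm_used == comb(8, 4) - 1  # all distinct, observed excluded

    def test_planted_effect_detected_and_null_not(self):
        geom = _geom(dims=(10, 10, 8))
        rng = np.random.default_rng(7)
        effect = np.zeros(geom.n_voxels)
        effect[100:140] = 3.0
        maps = []
        for i in range(20):
            v = rng.standard_normal(geom.n_voxels) + (effect if i < 10 else 0)
            maps.append(smooth_map(MetricMap(geom, v, "TSTAT"), 5.0))
        res = cluster_fwe_permutation(
            maps, _design(10, 10), voxel_p=1e-3, n_perm=300, seed=1
        )
        assert res.clusters["significant"].any()
        sig = res.significant_members(sign=1)
        found = np.unique(np.concatenate(sig))
        assert np.intersect1d(found, np.arange(100, 140)).size > 20


class TestSphereExtraction:
    def test_tiny_radius_returns_center_voxel(self):
        geom = _geom(vx=3.0)
        rng = np.random.default_rng(8)
        m = MetricMap(geom, rng.standard_normal(geom.n_voxels), "TSTAT")
        v = 17
        val, n = extract_sphere_mean(m, geom.mm_coords[v], 1.0)
        assert n == 1
        assert val == m.values[v]

    def test_constant_map_any_radius(self):
        geom = _geom(vx=3.0)
        m = MetricMap(geom, np.full(geom.n_voxels, 2.5), "TSTAT")
        val, n = extract_sphere_mean(m, geom.mm_coords[100], 7.0)
        assert val == pytest.approx(2.5)
        assert n > 1

    def test_paper_scale_sphere_on_3mm_grid_is_seven_voxels(self):
        # 3.5 mm radius at a voxel center on a 3 mm grid: center + 6 face
        # neighbors (distance 3 mm), diagonals at 4.24 mm excluded
        geom = _geom(dims=(9, 9, 9), vx=3.0)
        center_v = np.flatnonzero((geom.voxel_ijk == [4, 4, 4]).all(axis=1))[0]
        m = MetricMap(geom, np.ones(geom.n_voxels), "TSTAT")
        _, n = extract_sphere_mean(m, geom.mm_coords[center_v], 3.5)
        assert n == 7

    def test_empty_sphere_raises(self):
        geom = _geom(vx=3.0)
        m = MetricMap(geom, np.ones(geom.n_voxels), "TSTAT")
        with pytest.raises(ValueError):
            extract_sphere_mean(m, np.array([500.0, 500.0, 500.0]), 2.0)

    def test_cluster_mean_ignores_nan(self):
        geom = _geom()
        vals = np.arange(geom.n_voxels, dtype=float)
        vals[3] = np.nan
        m = MetricMap(geom, vals, "TSTAT")
        assert extract_cluster_mean(m, np.array([2, 3, 4])) == pytest.approx(3.0)


class TestPartialCorrelation:
    def test_orthogonal_covariate_equals_plain_pearson(self):
        rng = np.random.default_rng(9)
        n = 40
        x, y = rng.standard_normal((2, n))
        base = np.column_stack([np.ones(n), x, y])
        q, _ = np.linalg.qr(base)
        cov = (np.eye(n) - q @ q.T) @ rng.standard_normal(n)
        r, _ = partial_correlation(x, y, cov)
        from hemilat.connectivity import pearson_r

        # plain Pearson on demeaned data (the intercept is always removed)
        assert r == pytest.approx(pearson_r(x, y), abs=1e-10)

    def test_y_equal_to_covariate_is_undefined(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(30)
        cov = rng.standard_normal(30)
        r, p = partial_correlation(x, cov, cov)
        assert np.isnan(r) and np.isnan(p)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(11)
        n, k = 62, 1
        cov = rng.standard_normal((n, k))
        x = 0.5 * cov[:, 0] + rng.standard_normal(n)
        y = -0.3 * cov[:, 0] + 0.4 * x + rng.standard_normal(n)
        r, p = partial_correlation(x, y, cov)
        design = np.column_stack([np.ones(n), cov])
        bx = np.linalg.solve(design.T @ design, design.T @ x)
        by = np.linalg.solve(design.T @ design, design.T @ y)
        rx, ry = x - design @ bx, y - design @ by
        r_o = (rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry))
        t_o = r_o * np.sqrt((n - 2 - k) / (1 - r_o**2))
        p_o = 2 * stats.t.sf(abs(t_o), n - 2 - k)
        assert r == pytest.approx(r_o, abs=1e-10)
        assert p == pytest.approx(p_o, abs=1e-10)

    def test_matches_pingouin_cross_check(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(12)
        n = 45
        cov = rng.standard_normal(n)
        x = cov + rng.standard_normal(n)
        y = 0.5 * cov + 0.3 * x + rng.standard_normal(n)
        df = pd.DataFrame({"x": x, "y": y, "c": cov})
        ref = pingouin.partial_corr(df, x="x", y="y", covar="c")
        r, p = partial_correlation(x, y, cov)
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)

    def test_needs_enough_samples(self):
        with pytest.raises(ValueError):
            partial_correlation(np.ones(3), np.ones(3), np.ones((3, 1)))
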