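import numpy as np
import pytest

from hemilat.core_io import InsufficientDataError
from hemilat.denoise import (
    ConfoundSet,
    bandpass_filter,
    framewise_displacement,
    friston24_expand,
    regress_confounds,
    scrub_high_motion,
)

from conftest import make_series


class TestFriston24:
    def test_zero_motion_gives_zero_columns(self):
        assert np.all(friston24_expand(np.zeros((20, 6))) == 0)

    def test_constant_motion(self):
        m = np.full((10, 6), 3.0)
        x = friston24_expand(m)
        assert x.shape == (10, 24)
        assert np.all(x[:, 6:12] == 9.0)          # squared
        assert np.all(x[0, 12:] == 0.0)           # lagged first row padded
        assert np.all(x[1:, 12:18] == 3.0)
        assert np.all(x[1:, 18:24] == 9.0)

    def test_lag_column_definition(self):
        m = np.zeros((3, 6))
        m[:, 0] = [1.0, 2.0, 3.0]
        x = friston24_expand(m)
        assert np.array_equal(x[:, 12], [0.0, 1.0, 2.0])

    def test_wrong_shape_raises(self):
        with pytest.raises(ValueError):
            friston24_expand(np.zeros((10, 5)))


class TestRegressConfounds:
    def _confounds(self, rng, t):
        return ConfoundSet(
            motion6=rng.standard_normal((t, 6)) * 0.05,
            wm_signal=rng.standard_normal(t),
            csf_signal=rng.standard_normal(t),
        )

    def test_series_equal_to_confound_is_removed(self, small_geometry):
        rng = np.random.default_rng(0)
        t = 60
        conf = self._confounds(rng, t)
        data = np.tile(conf.wm_signal[:, None], (1, small_geometry.n_voxels))
        out = regress_confounds(make_series(small_geometry, data), conf)
        assert np.max(np.abs(out.data)) < 1e-8

    def test_residuals_orthogonal_to_design(self, small_geometry):
        rng = np.random.default_rng(1)
        t = 80
        conf = self._confounds(rng, t)
        s = make_series(small_geometry, rng.standard_normal((t, small_geometry.n_voxels)))
        out = regress_confounds(s, conf)
        from hemilat.denoise import _design_matrix

        x = _design_matrix(conf)
        assert np.max(np.abs(x.T @ out.data)) < 1e-8

    def test_orthogonal_confounds_leave_data_detrended_only(self):
        # oracle: explicit normal-equation projection on [1, trend] alone;
        # needs T > V + 2 so confounds orthogonal to every column exist
        from hemilat.core_io import partition_hemispheres
        from hemilat.synthetic_cohort import default_grid

        geom = partition_hemispheres(
            default_grid((4, 4, 3), 4.0), np.ones((4, 4, 3), dtype=bool)
        )
        rng = np.random.default_rng(2)
        t = 80
        data = rng.standard_normal((t, geom.n_voxels))
        # build WM/CSF confounds orthogonal to the data columns (and to
        # 1, trend); motion is exactly zero so its expansion contributes
        # nothing (zero columns are dropped by the pseudoinverse)
        base = np.column_stack([np.ones(t), np.linspace(-1, 1, t), data])
        q, _ = np.linalg.qr(base)
        null_space = np.eye(t) - q @ q.T
        raw = null_space @ rng.standard_normal((t, 2))
        conf = ConfoundSet(
            motion6=np.zeros((t, 6)), wm_signal=raw[:, 0], csf_signal=raw[:, 1]
        )
        out = regress_confounds(make_series(geom, data), conf)
        design = np.column_stack([np.ones(t), np.linspace(-1, 1, t), raw])
        beta = np.linalg.solve(design.T @ design, design.T @ data)
        expected = data - design @ beta
        assert np.allclose(out.data, expected, atol=1e-6)

    def test_variance_never_increases(self, small_geometry):
        rng = np.random.default_rng(3)
        t = 50
        conf = self._confounds(rng, t)
        s = make_series(small_geometry, rng.standard_normal((t, small_geometry.n_voxels)))
        out = regress_confounds(s, conf)
        assert np.all(out.data.var(axis=0) <= s.data.var(axis=0) + 1e-12)


class TestBandpass:
    def _probe(self, geometry, freq, t=400, tr=2.0):
        time = np.arange(t) * tr
        probe = np.sin(2 * np.pi * freq * time)
        data = np.tile(probe[:, None], (1, geometry.n_voxels))
        return make_series(geometry, data, tr_s=tr)

    def test_passband_preserved(self, small_geometry):
        s = self._probe(small_geometry, 0.05)
        out = bandpass_filter(s, 0.01, 0.1)
        mid = slice(100, 300)  # avoid edge transients
        ratio = out.data[mid, 0].std() / s.data[mid, 0].std()
        assert ratio >= 0.95

    def test_stopband_attenuated_at_twice_band_edge(self, small_geometry):
        s = self._probe(small_geometry, 0.2)
        out = bandpass_filter(s, 0.01, 0.1)
        mid = slice(100, 300)
        ratio = out.data[mid, 0].std() / s.data[mid, 0].std()
        assert ratio <= 0.10

    def test_constant_series_removed(self, small_geometry):
        data = np.full((100, small_geometry.n_voxels), 7.0)
        out = bandpass_filter(make_series(small_geometry, data), 0.01, 0.1)
        assert np.max(np.abs(out.data)) < 1e-6

    def test_band_outside_nyquist_raises(self, small_geometry):
        s = self._probe(small_geometry, 0.05)
        with pytest.raises(ValueError):
            bandpass_filter(s, 0.01, 0.3)  # Nyquist at TR=2 s is 0.25 Hz


class TestScrubbing:
    def test_fd_arithmetic_hand_oracle(self):
        motion = np.zeros((5, 6))
        motion[2, 0] = 1.0   # 1 mm translation level shift at frame 2
        motion[3, 4] = 0.01  # 0.01 rad rotation shift at frame 3
        fd = framewise_displacement(motion)
        assert fd[0] == 0.0
        assert fd[2] == pytest.approx(1.0)
        assert fd[3] == pytest.approx(1.0 + 0.01 * 50)  # translation back + rot

    def test_single_jump_removes_exactly_that_frame(self, small_geometry):
        rng = np.random.default_rng(0)
        t = 30
        s = make_series(small_geometry, rng.standard_normal((t, small_geometry.n_voxels)))
        motion = np.zeros((t, 6))
        motion[12:, 1] = 1.0  # level shift: FD spike only at frame 12
        out = scrub_high_motion(s, motion, fd_threshold_mm=0.5)
        assert out.n_frames == t - 1
        assert 12 not in out.kept_frames
        assert np.array_equal(out.data, np.delete(s.data, 12, axis=0))

    def test_zero_motion_removes_nothing(self, small_geometry):
        rng = np.random.default_rng(1)
        s = make_series(small_geometry, rng.standard_normal((20, small_geometry.n_voxels)))
        out = scrub_high_motion(s, np.zeros((20, 6)), 0.5)
        assert out.n_frames == 20

    def test_infinite_threshold_is_identity(self, small_geometry):
        rng = np.random.default_rng(2)
        s = make_series(small_geometry, rng.standard_normal((20, small_geometry.n_voxels)))
        motion = rng.standard_normal((20, 6))
        out = scrub_high_motion(s, motion, np.inf)
        assert np.array_equal(out.data, s.data)

    def test_too_few_surviving_frames_raises(self, small_geometry):
        rng = np.random.default_rng(3)
        t = 15
        s = make_series(small_geometry, rng.standard_normal((t, small_geometry.n_voxels)))
        motion = np.zeros((t, 6))
        motion[1::2, 0] = np.arange(1, 8) * 10.0  # large FD on many frames
        with pytest.raises(InsufficientDataError):
            scrub_high_motion(s, motion, 0.5)
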