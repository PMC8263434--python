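import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lapmotion import (
    SGConfig,
    VelocityBands,
    mean_kinematic_magnitudes,
    operative_time,
    path_length,
    sg_smooth,
    velocity_band_distribution,
)
from lapmotion.errors import ConfigurationError, SegmentTooShortError, UndefinedMetricError

from conftest import make_track, smooth_random_walk


def series_from(pos, fs=100.0):
    t = np.arange(pos.shape[0]) / fs
    return sg_smooth(np.asarray(pos, float), SGConfig(), t=t)


class TestSGSmooth:
    def test_linear_trajectory_derivatives(self):
        t = np.arange(0, 5, 0.01)
        pos = np.column_stack([2 + 3 * t, np.zeros_like(t), np.zeros_like(t)])
        s = sg_smooth(pos, t=t)
        np.testing.assert_allclose(s.d1[s.valid, 0], 3.0, atol=1e-10)
        np.testing.assert_allclose(s.d2[s.valid], 0.0, atol=1e-8)
        np.testing.assert_allclose(s.d3[s.valid], 0.0, atol=1e-6)

    def test_cubic_reproduced_exactly(self):
        t = np.arange(0, 5, 0.01)
        pos = np.column_stack([t**3, np.zeros_like(t), np.zeros_like(t)])
        s = sg_smooth(pos, t=t)
        np.testing.assert_allclose(s.pos_s[s.valid, 0], t[s.valid] ** 3, rtol=1e-10)
        np.testing.assert_allclose(s.d1[s.valid, 0], 3 * t[s.valid] ** 2, rtol=1e-9, atol=1e-9)
        np.testing.assert_allclose(s.d2[s.valid, 0], 6 * t[s.valid], rtol=1e-8, atol=1e-7)
        np.testing.assert_allclose(s.d3[s.valid, 0], 6.0, rtol=1e-6)

    def test_edge_frames_invalid(self):
        s = series_from(np.zeros((100, 3)))
        h = SGConfig().half_window
        assert not s.valid[:h].any() and not s.valid[-h:].any()
        assert s.valid[h:-h].all()

    def test_sg_beats_central_difference_under_noise(self, rng):
        """SG derivative of a noisy sine must outdo the finite-difference oracle."""
        fs = 100.0
        t = np.arange(0, 10, 1 / fs)
        x = np.sin(2 * np.pi * 0.8 * t)
        noisy = x + rng.normal(0, 0.05, t.size)
        pos = np.column_stack([noisy, np.zeros_like(t), np.zeros_like(t)])
        s = sg_smooth(pos, t=t)
        truth = 2 * np.pi * 0.8 * np.cos(2 * np.pi * 0.8 * t)
        sg_rmse = np.sqrt(np.mean((s.d1[s.valid, 0] - truth[s.valid]) ** 2))
        fd = np.gradient(noisy, 1 / fs)
        fd_rmse = np.sqrt(np.mean((fd[s.valid] - truth[s.valid]) ** 2))
        assert sg_rmse < fd_rmse

    def test_too_short_segment_raises(self):
        with pytest.raises(SegmentTooShortError):
            series_from(np.zeros((20, 3)))

    def test_jittered_timestamps_resampled(self, rng):
        t = np.arange(0, 5, 0.01) + rng.uniform(-0.002, 0.002, 500)
        t = np.sort(t)
        pos = np.column_stack([2 * t, np.zeros_like(t), np.zeros_like(t)])
        s = sg_smooth(pos, t=t, sample_rate=100.0)
        dts = np.diff(s.t)
        np.testing.assert_allclose(dts, dts[0], rtol=1e-9)
        np.testing.assert_allclose(s.d1[s.valid, 0], 2.0, atol=1e-6)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            SGConfig(poly_order=3, window_frames=30)
        with pytest.raises(ConfigurationError):
            SGConfig(poly_order=5, window_frames=5)


class TestPathLength:
    def test_straight_line_10cm(self, straight_series):
        # 2 cm/s; a 5-s in-box window covers exactly 10 cm of trajectory
        s = straight_series
        eps = 1e-9
        inside = (s.t >= 0.5 - eps) & (s.t <= 5.5 + eps)
        assert path_length(s, inside) == pytest.approx(0.10, rel=1e-6)

    def test_outside_half_excluded(self, straight_series):
        s = straight_series
        eps = 1e-9
        inside_full = (s.t >= 0.5 - eps) & (s.t <= 5.5 + eps)
        inside_half = (s.t >= 0.5 - eps) & (s.t <= 3.0 + eps)
        assert path_length(s, inside_half) == pytest.approx(
            path_length(s, inside_full) / 2, rel=1e-6
        )

    def test_matches_brute_force_oracle(self, rng):
        tr = smooth_random_walk(rng, n=1000)
        s = sg_smooth(tr)
        got = path_length(s, tr.inside)
        brute = 0.0
        for i in range(s.n_frames - 1):
            if s.valid[i] and s.valid[i + 1]:
                brute += float(np.sqrt(((s.pos_s[i + 1] - s.pos_s[i]) ** 2).sum())) / 100
        assert got == pytest.approx(brute, rel=1e-9)

    def test_rigid_motion_invariance(self, rng):
        from scipy.spatial.transform import Rotation

        tr = smooth_random_walk(rng, n=800)
        R = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        moved = make_track(tr.pos @ R.T + np.array([5.0, -2.0, 1.0]))
        a = path_length(sg_smooth(tr), tr.inside)
        b = path_length(sg_smooth(moved), moved.inside)
        assert b == pytest.approx(a, rel=1e-9)

    def test_sampling_rate_consistency(self):
        """Doubling the sampling rate of a smooth path changes metrics < 1%.

        The in-box window is pinned to [0.5, 19.5] s so both rates measure the
        same stretch of trajectory (edge-invalid margins differ in seconds).
        """

        def metrics(fs):
            t = np.arange(0, 20, 1 / fs)
            pos = np.column_stack(
                [np.sin(0.4 * t), 0.5 * np.cos(0.55 * t), 0.2 * np.sin(0.25 * t)]
            )
            s = sg_smooth(pos, t=t)
            inside = (s.t >= 0.5) & (s.t <= 19.5)
            v = np.linalg.norm(s.d1[s.valid & inside], axis=1).mean()
            return path_length(s, inside), v

        p1, v1 = metrics(100.0)
        p2, v2 = metrics(200.0)
        assert abs(p2 - p1) / p1 < 0.005
        assert abs(v2 - v1) / v1 < 0.01


class TestMeanMagnitudes:
    def test_constant_velocity_line(self, straight_series):
        v, a, j = mean_kinematic_magnitudes(straight_series)
        assert v == pytest.approx(2.0, rel=1e-9)
        assert a == pytest.approx(0.0, abs=1e-7)
        assert j == pytest.approx(0.0, abs=1e-5)

    def test_uniform_circle_closed_form(self):
        fs, w, r = 200.0, 2.0, 1.0
        t = np.arange(0, 10, 1 / fs)
        pos = np.column_stack([r * np.cos(w * t), r * np.sin(w * t), np.zeros_like(t)])
        s = sg_smooth(pos, t=t)
        v, a, _ = mean_kinematic_magnitudes(s)
        assert v == pytest.approx(r * w, rel=5e-3)
        assert a == pytest.approx(r * w**2, rel=5e-3)

    def test_quadratic_has_zero_jerk_cubic_constant(self):
        t = np.arange(0, 5, 0.01)
        quad = np.column_stack([t**2, np.zeros_like(t), np.zeros_like(t)])
        s = sg_smooth(quad, t=t)
        assert mean_kinematic_magnitudes(s).jerk == pytest.approx(0.0, abs=1e-6)
        cub = np.column_stack([0.5 * t**3, t**3, np.zeros_like(t)])
        s = sg_smooth(cub, t=t)
        # |d3| = ||(3, 6, 0)|| exactly, every valid frame
        assert mean_kinematic_magnitudes(s).jerk == pytest.approx(np.hypot(3, 6), rel=1e-8)

    def test_matches_direct_norm_oracle(self, rng):
        tr = smooth_random_walk(rng)
        s = sg_smooth(tr)
        v, a, j = mean_kinematic_magnitudes(s)
        assert v == pytest.approx(np.linalg.norm(s.d1[s.valid], axis=1).mean())
        assert a == pytest.approx(np.linalg.norm(s.d2[s.valid], axis=1).mean())
        assert j == pytest.approx(np.linalg.norm(s.d3[s.valid], axis=1).mean())


class TestVelocityBands:
    def test_all_idle(self):
        t = np.arange(0, 5, 0.01)
        pos = np.column_stack([0.4 * t, np.zeros_like(t), np.zeros_like(t)])
        frac = velocity_band_distribution(sg_smooth(pos, t=t))
        np.testing.assert_allclose(frac, [1, 0, 0, 0, 0], atol=1e-12)

    def test_four_way_split_forced_by_edges(self):
        """Frames at 1, 3, 6, 13 cm/s land in low/middle/high/very_high."""
        from lapmotion.kinematics import band_fractions

        speeds = np.repeat([1.0, 3.0, 6.0, 13.0], 25)
        frac = band_fractions(speeds, VelocityBands())
        np.testing.assert_allclose(frac, [0, 0.25, 0.25, 0.25, 0.25], atol=1e-12)

    def test_exact_edge_goes_to_upper_band(self):
        from lapmotion.kinematics import band_fractions

        frac = band_fractions(np.array([0.5]), VelocityBands())
        np.testing.assert_array_equal(frac, [0, 1, 0, 0, 0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 50, allow_nan=False), min_size=1, max_size=200))
    def test_fractions_always_sum_to_one(self, speeds):
        from lapmotion.kinematics import band_fractions

        frac = band_fractions(np.array(speeds), VelocityBands())
        assert abs(frac.sum() - 1.0) < 1e-12

    def test_empty_input_rejected(self):
        from lapmotion.kinematics import band_fractions

        with pytest.raises(UndefinedMetricError):
            band_fractions(np.array([]), VelocityBands())


class TestOperativeTime:
    def test_manifest_mode(self):
        assert operative_time([], start=0.0, end=960.0) == 960.0

    def test_inference_mode(self):
        tr1 = make_track(np.zeros((300, 3)))  # t in [0, 2.99]
        t2 = 3.0 + np.arange(0, 117.01, 0.01)
        tr2 = make_track(np.zeros((t2.size, 3)))
        tr2.t = t2
        assert operative_time([tr2]) == pytest.approx(117.0)
        assert operative_time([tr1, tr2]) == pytest.approx(120.0)

    def test_end_before_start_rejected(self):
        from lapmotion.errors import TrackValidationError

        with pytest.raises(TrackValidationError):
            operative_time([], start=10.0, end=5.0)
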