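import numpy as np
import pytest
from scipy import stats

from swayrisk import features, silhouette, synthetic
from swayrisk.depth_io import DepthFrame, DepthSequence
from swayrisk.features import (
    BalanceParameters,
    CentroidTrace,
    aggregate_trials,
    backproject,
    body_dispersion,
    centroid_max_speed,
    centroid_trace,
    centroid_variability,
    compute_centroid,
    extract_balance_parameters,
)
from swayrisk.silhouette import SilhouetteMask

from conftest import fast_render

INTR = (100.0, 120.0, 8.0, 6.0)


def _mask(shape, pixels):
    m = np.zeros(shape, bool)
    for v, u in pixels:
        m[v, u] = True
    return SilhouetteMask(mask=m, index=0)


class TestBackprojection:
    def test_optical_axis_pixel(self):
        grid = np.full((13, 17), 2000, np.uint16)
        pts = backproject(_mask((13, 17), [(6, 8)]), DepthFrame(grid, 0), INTR)
        np.testing.assert_allclose(pts, [[0.0, 0.0, 2.0]])

    def test_unit_offset_pixel(self):
        fx, fy, cx, cy = 100.0, 100.0, 8.0, 6.0
        grid = np.full((13, 120), 1000, np.uint16)
        pts = backproject(_mask((13, 120), [(6, int(cx + fx))]), DepthFrame(grid, 0), (fx, fy, cx, cy))
        np.testing.assert_allclose(pts, [[1.0, 0.0, 1.0]])

    def test_random_mask_matches_scalar_loop(self):
        rng = np.random.default_rng(2)
        grid = rng.integers(500, 5000, (20, 30)).astype(np.uint16)
        m = rng.random((20, 30)) < 0.3
        pts = backproject(SilhouetteMask(mask=m, index=0), DepthFrame(grid, 0), INTR)
        fx, fy, cx, cy = INTR
        expected = []
        for v in range(20):
            for u in range(30):
                if m[v, u]:
                    d = grid[v, u] / 1000.0
                    expected.append([(u - cx) * d / fx, (v - cy) * d / fy, d])
        np.testing.assert_allclose(sorted(pts.tolist()), sorted(expected))

    def test_empty_mask_empty_cloud(self):
        pts = backproject(_mask((4, 4), []), DepthFrame(np.zeros((4, 4), np.uint16), 0), INTR)
        assert pts.shape == (0, 3)
        assert compute_centroid(pts) is None


class TestCentroid:
    def test_mean_of_two_points(self):
        np.testing.assert_allclose(
            compute_centroid(np.array([[0, 0, 2], [2, 0, 2]], float)), [1, 0, 2]
        )

    def test_single_point_identity(self):
        np.testing.assert_allclose(compute_centroid(np.array([[1.5, -2, 3]])), [1.5, -2, 3])

    def test_large_cloud_matches_accumulation(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(1000, 3))
        acc = np.zeros(3)
        for p in pts:
            acc += p
        np.testing.assert_allclose(compute_centroid(pts), acc / 1000, atol=1e-12)


def _trace(xs, zs=None, rate=30.0, ys=None):
    xs = np.asarray(xs, float)
    zs = np.zeros_like(xs) if zs is None else np.asarray(zs, float)
    ys = np.zeros_like(xs) if ys is None else np.asarray(ys, float)
    return CentroidTrace(positions=np.column_stack([xs, ys, zs]), frame_rate_hz=rate)


class TestCentroidTraceGaps:
    def _gap_sequence(self):
        bg = np.full((30, 30), 4000, np.uint16)
        block_a = bg.copy()
        block_a[5:25, 4:14] = 2000
        block_c = bg.copy()
        block_c[5:25, 6:16] = 2000
        frames = [bg, block_a, bg, block_c]  # middle person frame empty
        return DepthSequence(
            frames=[DepthFrame(g, i) for i, g in enumerate(frames)],
            intrinsics=(100.0, 100.0, 15.0, 15.0),
            background_frames=1,
        )

    def test_interior_gap_linearly_interpolated(self):
        seq = self._gap_sequence()
        masks = silhouette.extract_all(seq)
        assert masks[1].empty
        trace = centroid_trace(seq, masks)
        assert len(trace) == 3
        np.testing.assert_allclose(
            trace.positions[1], (trace.positions[0] + trace.positions[2]) / 2, atol=1e-12
        )

    def test_all_empty_raises(self):
        bg = np.full((10, 10), 4000, np.uint16)
        seq = DepthSequence(
            frames=[DepthFrame(bg, 0), DepthFrame(bg, 1)], background_frames=1
        )
        with pytest.raises(ValueError, match="empty"):
            centroid_trace(seq, silhouette.extract_all(seq))


class TestCentroidVariability:
    def test_constant_trace_zero(self):
        assert centroid_variability(_trace(np.full(50, 0.3))) == pytest.approx(0.0, abs=1e-12)

    def test_sinusoid_closed_form(self):
        t = np.arange(300) / 30.0
        x = 0.02 * np.sin(2 * np.pi * 0.5 * t)  # whole number of periods
        assert centroid_variability(_trace(x)) == pytest.approx(0.02 / np.sqrt(2), rel=0.01)

    def test_random_walk_matches_two_pass_variance(self):
        rng = np.random.default_rng(6)
        x = np.cumsum(rng.normal(0, 0.001, 200))
        z = np.cumsum(rng.normal(0, 0.001, 200))
        got = centroid_variability(_trace(x, z))
        varx = ((x - x.mean()) ** 2).sum() / 199
        varz = ((z - z.mean()) ** 2).sum() / 199
        assert got == pytest.approx(np.sqrt(varx + varz), rel=1e-12)


class TestCentroidMaxSpeed:
    def test_constant_trace_zero(self):
        assert centroid_max_speed(_trace(np.full(20, 1.0))) == 0.0

    def test_linear_drift_exact(self):
        t = np.arange(100) / 30.0
        got = centroid_max_speed(_trace(0.05 * t))
        assert got == pytest.approx(0.05, abs=1e-6)

    def test_sinusoid_peak_speed(self):
        t = np.arange(300) / 30.0
        x = 0.02 * np.sin(2 * np.pi * 0.5 * t)
        got = centroid_max_speed(_trace(x), smooth_window=1)
        assert got == pytest.approx(2 * np.pi * 0.5 * 0.02, rel=0.02)

    def test_window_validation(self):
        with pytest.raises(ValueError):
            centroid_max_speed(_trace(np.zeros(10)), smooth_window=4)
        with pytest.raises(ValueError, match="shorter"):
            centroid_max_speed(_trace(np.zeros(3)), smooth_window=5)


def _eig_ratio_2x2(a, b, c):
    """Closed-form eigenvalues of [[a, b], [b, c]]."""
    half = np.sqrt(((a - c) / 2) ** 2 + b**2)
    lam1 = (a + c) / 2 + half
    lam2 = (a + c) / 2 - half
    return lam1 / lam2


class TestBodyDispersion:
    def test_isotropic_cloud_is_one(self):
        pts = np.array([[1, 0, 0], [-1, 0, 0], [0, 0, 1], [0, 0, -1]], float)
        assert body_dispersion(pts) == pytest.approx(1.0)

    def test_diagonal_covariance_ratio_four(self):
        pts = np.array([[2, 0, 0], [-2, 0, 0], [0, 0, 1], [0, 0, -1]], float)
        assert body_dispersion(pts) == pytest.approx(4.0)

    def test_rotation_invariance_and_closed_form(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(500, 3)) * [0.3, 1.0, 0.1]
        base = body_dispersion(pts)
        cov = np.cov(pts[:, 0], pts[:, 2], ddof=1)
        assert base == pytest.approx(_eig_ratio_2x2(cov[0, 0], cov[0, 1], cov[1, 1]), rel=1e-12)
        theta = np.deg2rad(30)
        rot = pts.copy()
        rot[:, 0] = pts[:, 0] * np.cos(theta) - pts[:, 2] * np.sin(theta)
        rot[:, 2] = pts[:, 0] * np.sin(theta) + pts[:, 2] * np.cos(theta)
        assert body_dispersion(rot) == pytest.approx(base, rel=1e-9)

    def test_degenerate_cloud_capped(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        assert body_dispersion(pts) == features.DISPERSION_CAP

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            body_dispersion(np.zeros((2, 3)))


class TestRenderedPipeline:
    def test_static_scene_parameters(self):
        trace = synthetic.SwayTrace(positions=np.zeros((60, 2)), frame_rate_hz=30.0)
        p = extract_balance_parameters(fast_render(trace).sequence)
        assert p.centroid_variability < 1e-6
        assert p.centroid_max_speed < 1e-6
        assert p.max_dispersion > 1.0

    def test_arm_event_increases_dispersion(self):
        still = np.zeros((60, 2))
        base = extract_balance_parameters(
            fast_render(synthetic.SwayTrace(positions=still, frame_rate_hz=30.0)).sequence
        )
        with_arms = extract_balance_parameters(
            fast_render(
                synthetic.SwayTrace(positions=still, frame_rate_hz=30.0, arm_events=((20, 40),))
            ).sequence
        )
        assert with_arms.max_dispersion > base.max_dispersion

    def test_variability_scales_with_amplitude(self):
        def measure(amp):
            profile = synthetic.SwayProfile(
                lateral_amplitude=amp, ap_amplitude=0.0, sway_frequency=0.5, seed=3
            )
            trace = synthetic.simulate_sway_trace(profile, duration_s=6.0)
            return extract_balance_parameters(fast_render(trace).sequence).centroid_variability

        v1, v2 = measure(0.008), measure(0.016)
        assert v2 / v1 == pytest.approx(2.0, rel=0.10)

    def test_translation_invariance_parallel_to_image_plane(self):
        profile = synthetic.SwayProfile(
            lateral_amplitude=0.015, ap_amplitude=0.0, sway_frequency=0.5, seed=3
        )
        trace = synthetic.simulate_sway_trace(profile, duration_s=5.0)
        p0 = extract_balance_parameters(fast_render(trace).sequence)
        shifted = synthetic.SwayTrace(
            positions=trace.positions + [0.15, 0.0], frame_rate_hz=trace.frame_rate_hz
        )
        p1 = extract_balance_parameters(fast_render(shifted).sequence)
        assert p1.centroid_variability == pytest.approx(p0.centroid_variability, rel=0.02)
        assert p1.centroid_max_speed == pytest.approx(p0.centroid_max_speed, rel=0.05)
        assert p1.max_dispersion == pytest.approx(p0.max_dispersion, rel=0.05)

    def test_amplitude_recovery_spearman(self):
        amplitudes = np.linspace(0.004, 0.03, 20)
        measured = []
        for k, amp in enumerate(amplitudes):
            profile = synthetic.SwayProfile(
                lateral_amplitude=amp, ap_amplitude=0.3 * amp, sway_frequency=0.5,
                velocity_noise_sd=0.002, seed=100 + k,
            )
            trace = synthetic.simulate_sway_trace(profile, duration_s=4.0)
            measured.append(
                extract_balance_parameters(fast_render(trace).sequence).centroid_variability
            )
        rho = stats.spearmanr(amplitudes, measured).statistic
        assert rho >= 0.9


class TestAggregateTrials:
    def test_idempotent_and_mean_and_symmetric(self):
        p1 = BalanceParameters(0.01, 0.02, 2.0)
        p2 = BalanceParameters(0.03, 0.04, 4.0)
        assert aggregate_trials(p1, p1) == p1
        mean = aggregate_trials(p1, p2)
        assert mean.as_tuple() == pytest.approx((0.02, 0.03, 3.0))
        assert aggregate_trials(p2, p1) == mean

    def test_parameter_invariants_enforced(self):
        with pytest.raises(ValueError):
            BalanceParameters(-0.1, 0.0, 2.0)
        with pytest.raises(ValueError):
            BalanceParameters(0.1, 0.0, 0.5)
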