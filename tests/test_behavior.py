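import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dnpop.behavior import (
    FD_STENCIL_9,
    BallRotationSeries,
    HeuristicThresholds,
    PoseSeries,
    compute_motion_energy,
    focal_length_from_fov,
    fov_from_focal,
    hysteresis_filter,
    integrate_fictive_trajectory,
    label_behavior_heuristic,
)


def make_pose(joints, tarsus=None, fs=100.0):
    n = joints.shape[2]
    return PoseSeries(
        joint_positions=joints,
        frame_times=np.arange(n) / fs,
        front_joints=[0, 1],
        hind_joints=[2, 3],
        front_tarsus_height=np.zeros(n) if tarsus is None else tarsus,
    )


class TestMotionEnergy:
    def test_static_pose_zero_energy(self):
        me = compute_motion_energy(make_pose(np.zeros((4, 3, 500))))
        assert np.allclose(me.total, 0.0)
        assert np.allclose(me.front, 0.0)

    def test_front_only_motion(self):
        t = np.arange(500) / 100.0
        joints = np.zeros((4, 3, 500))
        joints[0, 0] = np.sin(2 * np.pi * 2.0 * t)
        me = compute_motion_energy(make_pose(joints))
        assert np.allclose(me.hind, 0.0, atol=1e-9)
        assert me.front.mean() > 0.0
        assert np.allclose(me.total, me.front, atol=1e-9)

    def test_stencil_exact_on_linear_motion(self):
        # the length-9 central stencil reproduces a constant derivative exactly
        v = 0.37
        ramp = v * np.arange(100)
        deriv = np.convolve(ramp, FD_STENCIL_9, mode="valid")
        assert np.allclose(deriv, v, atol=1e-10)

    def test_translation_invariance(self):
        rng = np.random.default_rng(0)
        joints = rng.standard_normal((4, 3, 400)).cumsum(axis=2) * 0.01
        a = compute_motion_energy(make_pose(joints))
        b = compute_motion_energy(make_pose(joints + 11.0))
        assert np.allclose(a.total, b.total, atol=1e-10)

    def test_too_few_frames_raises(self):
        with pytest.raises(ValueError):
            compute_motion_energy(make_pose(np.zeros((4, 3, 5))))


class TestHysteresis:
    def test_short_excursion_suppressed(self):
        lab = np.array(["a"] * 100 + ["b"] * 49 + ["a"] * 100)
        assert (hysteresis_filter(lab, 50) == "a").all()

    def test_full_run_accepted_at_onset(self):
        lab = np.array(["a"] * 100 + ["b"] * 50 + ["a"] * 100)
        out = hysteresis_filter(lab, 50)
        assert out[99] == "a" and out[100] == "b" and out[149] == "b" and out[150] == "a"

    def test_constant_unchanged(self):
        lab = np.array(["x"] * 30)
        assert (hysteresis_filter(lab, 50) == "x").all()

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.sampled_from("abc"), min_size=1, max_size=400), st.integers(2, 60))
    def test_idempotent_and_min_run(self, seq, min_run):
        lab = np.array(seq)
        once = hysteresis_filter(lab, min_run)
        assert (hysteresis_filter(once, min_run) == once).all()
        # internal runs (all but the first and last) are >= min_run long
        change = np.flatnonzero(once[1:] != once[:-1]) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [once.size]])
        for s, e in list(zip(starts, ends))[1:-1]:
            assert e - s >= min_run


class TestLabelCascade:
    def _series(self, n=2000):
        joints = np.zeros((4, 3, n))
        tarsus = np.zeros(n)
        fwd = np.zeros(n)
        return joints, tarsus, fwd

    def test_walking_resting_and_front_split(self):
        n = 3000
        t = np.arange(n) / 100.0
        joints, tarsus, fwd = self._series(n)
        # 0-10 s: walking at 1 mm/s; 10-20 s: rest; 20-30 s: front movement
        fwd[:1000] = 1.0
        osc = 2.0 * np.sin(2 * np.pi * 2.5 * t)
        joints[0, 0, :1000] = osc[:1000]
        joints[2, 0, :1000] = osc[:1000]
        joints[0, 0, 2000:] = osc[2000:]
        joints[1, 0, 2000:] = osc[2000:]
        tarsus[2000:2500] = 0.15  # grooming; then rubbing at 0.01
        tarsus[2500:] = 0.01
        pose = make_pose(joints, tarsus)
        ball = BallRotationSeries(fwd, np.zeros(n), np.zeros(n), np.arange(n) / 100.0)
        me = compute_motion_energy(pose)
        labels = label_behavior_heuristic(me, ball, pose)
        mid = slice(200, 800)
        assert (labels[mid] == "walking").mean() > 0.95
        assert (labels[1200:1800] == "resting").mean() > 0.95
        assert (labels[2100:2400] == "head_grooming").mean() > 0.9
        assert (labels[2600:2950] == "front_leg_rubbing").mean() > 0.9

    def test_posterior_movements(self):
        n = 2000
        t = np.arange(n) / 100.0
        joints, tarsus, fwd = self._series(n)
        joints[2, 0] = 2.0 * np.sin(2 * np.pi * 2.5 * t)
        joints[3, 0] = 2.0 * np.sin(2 * np.pi * 2.5 * t + 1.0)
        pose = make_pose(joints, tarsus)
        ball = BallRotationSeries(fwd, np.zeros(n), np.zeros(n), np.arange(n) / 100.0)
        labels = label_behavior_heuristic(compute_motion_energy(pose), ball, pose)
        assert (labels[200:1800] == "posterior_movements").mean() > 0.95

    def test_each_frame_gets_exactly_one_label(self, small_fly):
        tr = small_fly.trials[0]
        me = compute_motion_energy(tr.pose)
        labels = label_behavior_heuristic(me, tr.ball, tr.pose)
        assert labels.shape == tr.labels.shape
        valid = {
            "walking",
            "resting",
            "head_grooming",
            "front_leg_rubbing",
            "posterior_movements",
            "unlabeled",
        }
        assert set(np.unique(labels)) <= valid


class TestOptics:
    def test_printed_focal_length(self):
        assert focal_length_from_fov(6.6, 8.74) == pytest.approx(43.18, abs=0.01)

    def test_round_trip(self):
        for H, alpha in [(6.6, 8.74), (2.32, 3.0), (5.8, 12.0)]:
            assert fov_from_focal(H, focal_length_from_fov(H, alpha)) == pytest.approx(alpha)

    def test_reduced_sensor_fov(self):
        # closed form with the reduced 2.32 mm sensor height
        assert fov_from_focal(2.32, 43.18) == pytest.approx(3.078, abs=0.005)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            focal_length_from_fov(-1.0, 10.0)
        with pytest.raises(ValueError):
            focal_length_from_fov(6.6, 200.0)


class TestTrajectory:
    def _ball(self, fwd, yaw, dt=0.01):
        n = fwd.size
        return BallRotationSeries(fwd, yaw, np.zeros(n), np.arange(n) * dt)

    def test_zero_velocities_stationary(self):
        tr = integrate_fictive_trajectory(self._ball(np.zeros(100), np.zeros(100)))
        assert np.allclose(tr.x, 0.0) and np.allclose(tr.y, 0.0)

    def test_straight_path_length(self):
        v, T, dt = 4.0, 10.0, 0.01
        n = int(T / dt)
        tr = integrate_fictive_trajectory(self._ball(np.full(n, v), np.zeros(n)))
        assert tr.x[-1] == pytest.approx(v * (T - dt), rel=1e-9)
        assert np.allclose(tr.y, 0.0)

    def test_circular_motion_radius(self):
        v, omega, dt = 4.0, 1.3, 0.01
        n = int(20 / dt)
        tr = integrate_fictive_trajectory(self._ball(np.full(n, v), np.full(n, omega)))
        r = v / omega
        dev = np.abs(np.hypot(tr.x, tr.y - r) - r)
        assert dev.max() < 0.01 * r

    def test_path_length_matches_speed_integral(self):
        rng = np.random.default_rng(0)
        from scipy.ndimage import gaussian_filter1d

        n = 5000
        fwd = 3.0 + gaussian_filter1d(rng.standard_normal(n), 50) * 2.0
        yaw = gaussian_filter1d(rng.standard_normal(n), 50) * 1.0
        tr = integrate_fictive_trajectory(self._ball(fwd, yaw))
        path = np.hypot(np.diff(tr.x), np.diff(tr.y)).sum()
        integral = np.abs(fwd[:-1]).sum() * 0.01
        assert path == pytest.approx(integral, rel=0.005)

    def test_heading_wrapped(self):
        n = 2000
        tr = integrate_fictive_trajectory(self._ball(np.zeros(n), np.full(n, 2.0)))
        assert tr.heading.max() <= np.pi and tr.heading.min() >= -np.pi

    def test_non_uniform_grid_raises(self):
        ball = BallRotationSeries(
            np.zeros(10), np.zeros(10), np.zeros(10), np.concatenate([[0.0], np.cumsum(np.linspace(0.01, 0.03, 9))])
        )
        with pytest.raises(ValueError):
            integrate_fictive_trajectory(ball)
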