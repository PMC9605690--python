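"""Rule-based behavior labeling and fictive-trajectory geometry.

Implements the heuristic labeling cascade used to classify tethered-fly
behavior from 3D-pose-derived motion energy, spherical-treadmill rotations
and front-tarsus height, the run-length hysteresis filter, pinhole-optics
helpers for the treadmill camera, and integration of ball rotations into a
fictive 2D walking trajectory.

The cascade applies, in order: walking (filtered forward velocity above
0.5 mm/s), resting (total motion energy below 0.3), front movements (front
energy > 0.2 and hind energy < 0.2, split into head grooming vs front leg
rubbing by tarsus height at 0.05) and posterior movements (the converse).
A hysteresis filter that only accepts a state holding for at least 50
consecutive frames (0.5 s at 100 Hz) is applied after each stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

__all__ = [
    "BEHAVIOR_STATES",
    "UNLABELED",
    "PoseSeries",
    "MotionEnergy",
    "BallRotationSeries",
    "HeuristicThresholds",
    "Trajectory",
    "compute_motion_energy",
    "label_behavior_heuristic",
    "hysteresis_filter",
    "focal_length_from_fov",
    "fov_from_focal",
    "integrate_fictive_trajectory",
]

#: Canonical behavior labels, in the fixed tie-break/reporting order.
BEHAVIOR_STATES = (
    "walking",
    "resting",
    "head_grooming",
    "front_leg_rubbing",
    "posterior_movements",
)
UNLABELED = "unlabeled"

# 8th-order central finite-difference first-derivative stencil (length 9),
# for unit sample spacing.
FD_STENCIL_9 = np.array(
    [-1 / 280, 4 / 105, -1 / 5, 4 / 5, 0.0, -4 / 5, 1 / 5, -4 / 105, 1 / 280]
)


@dataclass
class PoseSeries:
    """Pose-derived per-frame series at the behavior rate (100 Hz).

    ``joint_positions`` is joint x axis x frame; ``front_joints`` and
    ``hind_joints`` index rows belonging to the front-leg and hind-leg joint
    sets.  ``front_tarsus_height`` is the left/right mean front tarsus height
    in the aligned-pose convention in which the 0.05 grooming/rubbing
    threshold applies.
    """

    joint_positions: np.ndarray
    frame_times: np.ndarray
    front_joints: list[int]
    hind_joints: list[int]
    front_tarsus_height: np.ndarray

    def __post_init__(self) -> None:
        self.joint_positions = np.asarray(self.joint_positions, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.joint_positions.ndim != 3:
            raise ValueError("joint_positions must be joint x axis x frame")
        dtv = np.diff(self.frame_times)
        if dtv.size and (dtv.max() - dtv.min()) > 0.01 * dtv.mean():
            raise ValueError("frame times must be uniformly spaced within 1%")

    @property
    def rate(self) -> float:
        return 1.0 / float(np.mean(np.diff(self.frame_times)))


@dataclass
class MotionEnergy:
    total: np.ndarray
    front: np.ndarray
    hind: np.ndarray


@dataclass
class BallRotationSeries:
    """Spherical-treadmill rotation velocities at 100 Hz.

    forward is in mm/s (the 0.5 mm/s walking threshold applies to it);
    yaw and roll are angular velocities in rad/s, positive yaw = right turn.
    """

    forward: np.ndarray
    yaw: np.ndarray
    roll: np.ndarray
    frame_times: np.ndarray

    def __post_init__(self) -> None:
        for name in ("forward", "yaw", "roll", "frame_times"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not all(
            np.all(np.isfinite(getattr(self, name)))
            for name in ("forward", "yaw", "roll")
        ):
            raise ValueError("ball rotation series must be finite")


@dataclass(frozen=True)
class HeuristicThresholds:
    """Thresholds of the labeling cascade (printed units)."""

    v_walk: float = 0.5  # mm/s
    me_rest: float = 0.3
    me_front: float = 0.2
    me_hind: float = 0.2
    tarsus_split: float = 0.05
    min_run: int = 50  # frames
    butterworth_order: int = 10
    butterworth_fc: float = 4.0  # Hz
    fd_length: int = 9


@dataclass
class Trajectory:
    x: np.ndarray
    y: np.ndarray
    heading: np.ndarray
    times: np.ndarray


def _lowpass(series: np.ndarray, fs: float, thresholds: HeuristicThresholds) -> np.ndarray:
    sos = _sig.butter(
        thresholds.butterworth_order, thresholds.butterworth_fc, btype="low", fs=fs, output="sos"
    )
    # zero-phase so behavior labels do not lag the kinematics
    return _sig.sosfiltfilt(sos, series, axis=-1)


def compute_motion_energy(
    pose: PoseSeries, thresholds: HeuristicThresholds = HeuristicThresholds()
) -> MotionEnergy:
    """Per-frame motion energy from joint positions.

    Each joint coordinate is convolved with the length-9 central
    finite-difference first-derivative stencil; the L1 norm is taken across
    axes and low-pass filtered (Butterworth order 10, fc 4 Hz, zero phase).
    Total/front/hind energies sum the per-joint energies over all joints,
    the front-leg joints and the hindleg joints respectively.
    """
    pos = pose.joint_positions
    n_frames = pos.shape[2]
    if n_frames < thresholds.fd_length:
        raise ValueError("fewer frames than the derivative stencil length")
    fs = pose.rate
    # 'same' convolution with edge replication to avoid boundary spikes
    pad = FD_STENCIL_9.size // 2
    padded = np.pad(pos, ((0, 0), (0, 0), (pad, pad)), mode="edge")
    deriv = _sig.fftconvolve(padded, FD_STENCIL_9[None, None, :], mode="valid", axes=2)
    per_joint = np.abs(deriv).sum(axis=1)  # L1 across axes
    per_joint = _lowpass(per_joint, fs, thresholds)
    per_joint = np.maximum(per_joint, 0.0)
    return MotionEnergy(
        total=per_joint.sum(axis=0),
        front=per_joint[pose.front_joints].sum(axis=0),
        hind=per_joint[pose.hind_joints].sum(axis=0),
    )


def hysteresis_filter(labels: np.ndarray, min_run: int = 50) -> np.ndarray:
    """Suppress state changes shorter than ``min_run`` frames.

    The output only switches to a new state when the input holds that state
    for at least ``min_run`` consecutive frames; the switch takes effect at
    the first frame of the qualifying run.  Idempotent; every internal run
    of the output (except possibly the first) has length >= min_run.
    """
    labels = np.asarray(labels)
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    if labels.size == 0 or min_run == 1:
        return labels.copy()
    out = labels.copy()
    # run-length encode
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    current = labels[0]
    for s, e in zip(starts, ends):
        if labels[s] == current:
            continue
        if e - s >= min_run:
            current = labels[s]
        else:
            out[s:e] = current
    return out


def label_behavior_heuristic(
    me: MotionEnergy,
    ball: BallRotationSeries,
    pose: PoseSeries,
    thresholds: HeuristicThresholds = HeuristicThresholds(),
    forward_prefiltered: bool = False,
) -> np.ndarray:
    """Heuristic behavior labels on the 100 Hz grid.

    Applies the threshold cascade (walking -> resting -> front/posterior
    movements -> grooming/rubbing split), re-running the hysteresis filter on
    the cumulative label map after each stage.  Frames matching no rule stay
    ``unlabeled``.
    """
    n = me.total.size
    if ball.forward.size != n or pose.front_tarsus_height.size != n:
        raise ValueError("motion energy, ball and pose series must share one grid")
    fs = pose.rate
    fwd = ball.forward if forward_prefiltered else _lowpass(ball.forward, fs, thresholds)

    labels = np.full(n, UNLABELED, dtype=object)
    labels[fwd > thresholds.v_walk] = "walking"
    labels = hysteresis_filter(labels, thresholds.min_run)

    free = labels == UNLABELED
    labels[free & (me.total < thresholds.me_rest)] = "resting"
    labels = hysteresis_filter(labels, thresholds.min_run)

    free = labels == UNLABELED
    front_move = free & (me.front > thresholds.me_front) & (me.hind < thresholds.me_hind)
    posterior = free & (me.front < thresholds.me_front) & (me.hind > thresholds.me_hind)
    # front movements split by tarsus height: raised tarsi -> head grooming
    labels[front_move & (pose.front_tarsus_height > thresholds.tarsus_split)] = "head_grooming"
    labels[front_move & (pose.front_tarsus_height <= thresholds.tarsus_split)] = "front_leg_rubbing"
    labels[posterior] = "posterior_movements"
    labels = hysteresis_filter(labels, thresholds.min_run)
    return labels.astype("U20")


def focal_length_from_fov(H: float, alpha_deg: float) -> float:
    """Pinhole focal length (mm) from sensor height H (mm) and vertical
    angular field of view alpha (degrees): f = H / (2 tan(alpha/2))."""
    if H <= 0:
        raise ValueError("sensor height must be positive")
    if not 0 < alpha_deg < 180:
        raise ValueError("field of view must be in (0, 180) degrees")
    return H / (2.0 * np.tan(np.deg2rad(alpha_deg) / 2.0))


def fov_from_focal(H: float, f: float) -> float:
    """Inverse of :func:`focal_length_from_fov`; returns alpha in degrees."""
    if H <= 0 or f <= 0:
        raise ValueError("H and f must be positive")
    return float(np.rad2deg(2.0 * np.arctan(H / (2.0 * f))))


def integrate_fictive_trajectory(
    ball: BallRotationSeries,
    ball_radius_mm: float | None = None,
) -> Trajectory:
    """Integrate treadmill rotations into a fictive 2D path.

    Heading is the integral of yaw velocity (wrapped to (-pi, pi]); each
    step advances the position by the body-frame displacement (forward
    velocity along the heading, plus a lateral component from roll when a
    ball radius is given) rotated into the world frame.  The midpoint
    heading is used within each step for second-order accuracy.
    """
    t = ball.frame_times
    dtv = np.diff(t)
    if dtv.size and (dtv.max() - dtv.min()) > 0.01 * dtv.mean():
        raise ValueError("trajectory integration requires a uniform time grid")
    dt = float(dtv.mean()) if dtv.size else 0.0
    heading_raw = np.concatenate([[0.0], np.cumsum(ball.yaw[:-1] * dt)])
    mid = heading_raw + 0.5 * ball.yaw * dt
    vx_body = ball.forward
    vy_body = (
        ball.roll * ball_radius_mm if ball_radius_mm is not None else np.zeros_like(ball.forward)
    )
    dx = (vx_body * np.cos(mid) - vy_body * np.sin(mid)) * dt
    dy = (vx_body * np.sin(mid) + vy_body * np.cos(mid)) * dt
    x = np.concatenate([[0.0], np.cumsum(dx[:-1])])
    y = np.concatenate([[0.0], np.cumsum(dy[:-1])])
    heading = np.angle(np.exp(1j * heading_raw))
    return Trajectory(x=x, y=y, heading=heading, times=t.copy())
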