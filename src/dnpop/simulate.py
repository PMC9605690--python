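"""Synthetic experiment generator with planted encoding ground truth.

Generates complete fictive experiments with the statistical structure the
analysis stages assume: a semi-Markov behavior sequence with state-specific
dwell times and transition biases (rest -> walk, head grooming -> front leg
rubbing), treadmill kinematics consistent with the labels (forward speed
above the walking threshold, raised-cosine turn bouts within walking), a
pose proxy whose motion energy and tarsus height cross the printed
classifier thresholds, an alternating air/ACV/MSC odor schedule that shifts
behavior statistics, and neural populations whose %ΔF/F traces are
crf-convolved weighted sums of behavior/rotation/odor regressors plus white
Gaussian noise.  Every neuron carries a planted encoding class and weight
vector, so each downstream analysis can be scored by parameter recovery.

All outputs are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .behavior import BEHAVIOR_STATES, BallRotationSeries, PoseSeries
from .design import build_regressors
from .signals import (
    CRFKernel,
    TraceMatrix,
    convolve_with_crf,
    make_crf_kernel,
    resample_to_neural,
)

__all__ = [
    "GeneratorConfig",
    "GroundTruthNeuron",
    "TrialRecording",
    "FlyRecording",
    "Experiment",
    "simulate_behavior_and_stimuli",
    "simulate_neural_traces",
    "generate_experiment",
]

ENCODING_CLASSES = (
    "walk",
    "head_groom",
    "rest",
    "turn_left",
    "turn_right",
    "speed",
    "odor_acv",
    "odor_msc",
    "none",
)

#: regressor driven by each planted class
CLASS_REGRESSOR = {
    "walk": "walking",
    "head_groom": "head_grooming",
    "rest": "resting",
    "turn_left": "yaw_left",
    "turn_right": "yaw_right",
    "speed": "forward",
    "odor_acv": "odor_acv",
    "odor_msc": "odor_msc",
}

_DEFAULT_DWELL = {
    "walking": 5.0,
    "resting": 4.0,
    "head_grooming": 3.0,
    "front_leg_rubbing": 2.5,
    "posterior_movements": 2.5,
}

# transition probabilities between behavior states; rows sum to 1.  Rest is
# predominantly followed by walking and head grooming predominantly by front
# leg rubbing, matching the sequential statistics the disambiguation analysis
# has to untangle.
_DEFAULT_TRANSITIONS = {
    "walking": {"resting": 0.50, "head_grooming": 0.20, "posterior_movements": 0.20, "front_leg_rubbing": 0.10},
    "resting": {"walking": 0.60, "head_grooming": 0.25, "posterior_movements": 0.10, "front_leg_rubbing": 0.05},
    "head_grooming": {"front_leg_rubbing": 0.60, "resting": 0.20, "walking": 0.15, "posterior_movements": 0.05},
    "front_leg_rubbing": {"resting": 0.40, "walking": 0.30, "head_grooming": 0.20, "posterior_movements": 0.10},
    "posterior_movements": {"walking": 0.40, "resting": 0.40, "head_grooming": 0.15, "front_leg_rubbing": 0.05},
}

_DEFAULT_PROPORTIONS = {
    "walk": 0.30,
    "head_groom": 0.12,
    "rest": 0.04,
    "turn_left": 0.07,
    "turn_right": 0.07,
    "speed": 0.05,
}

_DEFAULT_AMPLITUDES = {
    "walk": 5.0,
    "head_groom": 6.0,
    "rest": 5.0,
    "turn_left": 5.0,
    "turn_right": 5.0,
    "speed": 0.8,  # per mm/s of (convolved) forward speed
    "odor_acv": 6.0,
    "odor_msc": 6.0,
}

# class-conditional ROI position distributions in the connective plane
# (x medial-lateral, z dorsal-ventral, micrometres): mean and std.
_DEFAULT_ROI_DIST = {
    "walk": ((0.0, 42.0), (16.0, 7.0)),
    "head_groom": ((0.0, 12.0), (14.0, 5.0)),
    "rest": ((0.0, 25.0), (15.0, 10.0)),
    "turn_left": ((-16.0, 34.0), (7.0, 7.0)),
    "turn_right": ((16.0, 34.0), (7.0, 7.0)),
    "speed": ((0.0, 30.0), (12.0, 8.0)),
    "odor_acv": ((0.0, 20.0), (12.0, 8.0)),
    "odor_msc": ((0.0, 20.0), (12.0, 8.0)),
    "none": ((0.0, 28.0), (20.0, 14.0)),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of a synthetic experiment.

    Defaults mirror the scale of the original recordings: five flies,
    five 9 min trials per fly at a ~16 Hz neural and 100 Hz behavior rate,
    75-95 ROIs per fly.
    """

    seed: int = 0
    n_flies: int = 5
    n_trials: int = 5
    trial_duration: float = 540.0
    neural_rate: float = 16.4
    behavior_rate: float = 100.0
    n_neurons_range: tuple[int, int] = (75, 95)
    dwell_means: dict = field(default_factory=lambda: dict(_DEFAULT_DWELL))
    dwell_shape: float = 4.0
    dwell_min: float = 0.8
    transitions: dict = field(default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_TRANSITIONS.items()})
    # odor schedule: lead-in of humid air, then alternating odor/air blocks
    odor_lead_in: float = 60.0
    odor_on: float = 15.0
    odor_off: float = 45.0
    # odor modulation of behavior statistics
    acv_walk_multiplier: float = 1.6
    acv_speed_multiplier: float = 1.3
    acv_turn_multiplier: float = 0.6
    msc_walk_multiplier: float = 0.8
    # kinematics
    forward_speed_mean: float = 7.0
    forward_speed_std: float = 1.5
    turn_rate_hz: float = 0.25
    turn_amplitude: float = 2.5
    turn_duration: tuple[float, float] = (1.0, 2.0)
    # neural model
    class_proportions: dict = field(default_factory=lambda: dict(_DEFAULT_PROPORTIONS))
    n_odor_neurons: int = 2
    amplitudes: dict = field(default_factory=lambda: dict(_DEFAULT_AMPLITUDES))
    noise_sigma: float = 1.0
    photobleach_drift: float = 0.0  # %ΔF/F drop per trial, linear
    roi_distributions: dict = field(default_factory=lambda: {k: v for k, v in _DEFAULT_ROI_DIST.items()})
    crf_a: float = 7.4
    crf_b: float = 0.3

    @classmethod
    def from_dict(cls, raw: dict) -> "GeneratorConfig":
        """Build a config from a YAML/JSON-style dict (lists -> tuples)."""
        raw = dict(raw)
        for key in ("n_neurons_range", "turn_duration"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "roi_distributions" in raw:
            raw["roi_distributions"] = {
                k: tuple(tuple(pair) for pair in v)
                for k, v in raw["roi_distributions"].items()
            }
        return cls(**raw)

    def behavior_times(self) -> np.ndarray:
        n = int(round(self.trial_duration * self.behavior_rate))
        return np.arange(n) / self.behavior_rate

    def neural_times(self) -> np.ndarray:
        n = int(np.floor((self.trial_duration - 1.0 / self.behavior_rate) * self.neural_rate))
        return np.arange(n) / self.neural_rate

    def kernel(self) -> CRFKernel:
        return make_crf_kernel(self.crf_a, self.crf_b, dt=1.0 / self.behavior_rate)


@dataclass
class GroundTruthNeuron:
    neuron_id: int
    encoding_class: str
    weights: dict[str, float]
    noise_sigma: float
    x: float
    z: float


@dataclass
class TrialRecording:
    """One trial's aligned neural, behavioral, kinematic and stimulus data."""

    fly_id: int
    trial_id: int
    traces: TraceMatrix
    labels: np.ndarray  # per behavior frame
    label_times: np.ndarray
    ball: BallRotationSeries
    pose: PoseSeries
    odor_intervals: list  # (start, end, stimulus) covering the trial
    roi_positions: np.ndarray  # neuron x (x, z)


@dataclass
class FlyRecording:
    fly_id: int
    ground_truth: list[GroundTruthNeuron]
    trials: list[TrialRecording]

    def ground_truth_frame(self) -> pd.DataFrame:
        rows = []
        for gt in self.ground_truth:
            row = {
                "fly_id": self.fly_id,
                "neuron_id": gt.neuron_id,
                "encoding_class": gt.encoding_class,
                "noise_sigma": gt.noise_sigma,
                "x": gt.x,
                "z": gt.z,
            }
            for name, w in gt.weights.items():
                row[f"w_{name}"] = w
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class Experiment:
    config: GeneratorConfig
    flies: list[FlyRecording]

    def ground_truth_frame(self) -> pd.DataFrame:
        return pd.concat(
            [f.ground_truth_frame() for f in self.flies], ignore_index=True
        ).fillna(0.0)


def _odor_schedule(cfg: GeneratorConfig) -> list[tuple[float, float, str]]:
    """Alternating humid-air / ACV / air / MSC blocks covering one trial."""
    intervals: list[tuple[float, float, str]] = []
    t = 0.0
    end = cfg.trial_duration
    intervals.append((0.0, min(cfg.odor_lead_in, end), "air"))
    t = cfg.odor_lead_in
    odors = ("ACV", "MSC")
    i = 0
    while t < end:
        o_end = min(t + cfg.odor_on, end)
        intervals.append((t, o_end, odors[i % 2]))
        t = o_end
        if t >= end:
            break
        a_end = min(t + cfg.odor_off, end)
        intervals.append((t, a_end, "air"))
        t = a_end
        i += 1
    return intervals


def _stimulus_at(intervals: list[tuple[float, float, str]], t: float) -> str:
    for start, end, name in intervals:
        if start <= t < end:
            return name
    return "air"


def _raised_cosine(n: int) -> np.ndarray:
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / max(n - 1, 1)))


def _smooth_noise(rng: np.random.Generator, n: int, sigma: float, smooth_frames: float = 30.0) -> np.ndarray:
    return gaussian_filter1d(rng.standard_normal(n), smooth_frames) * sigma * np.sqrt(
        2.0 * np.sqrt(np.pi) * smooth_frames
    )


def simulate_behavior_and_stimuli(
    cfg: GeneratorConfig, rng: np.random.Generator
) -> tuple[np.ndarray, BallRotationSeries, PoseSeries, list]:
    """Simulate one trial's labels, treadmill kinematics, pose proxy and
    odor schedule.

    The behavior sequence is semi-Markov: states draw gamma dwell times
    (shape ``dwell_shape``, mean per state, floored at ``dwell_min``) and
    successors from the configured transition matrix.  Odor presence
    reweights transitions toward (ACV) or away from (MSC) walking, scales
    forward speed and straightens the path under ACV.
    """
    times = cfg.behavior_times()
    n = times.size
    fs = cfg.behavior_rate
    odor_intervals = _odor_schedule(cfg)

    for state, mean in cfg.dwell_means.items():
        if mean <= 0:
            raise ValueError(f"dwell mean for {state} must be positive")

    # --- semi-Markov state sequence -------------------------------------
    labels = np.empty(n, dtype="U20")
    state = "resting"
    t_idx = 0
    while t_idx < n:
        stim = _stimulus_at(odor_intervals, times[t_idx])
        mean = cfg.dwell_means[state]
        if state == "walking" and stim == "ACV":
            mean *= cfg.acv_walk_multiplier
        dwell = max(
            cfg.dwell_min,
            rng.gamma(cfg.dwell_shape, mean / cfg.dwell_shape),
        )
        n_frames = max(int(round(dwell * fs)), 1)
        labels[t_idx : t_idx + n_frames] = state
        t_idx += n_frames
        if t_idx >= n:
            break
        probs = dict(cfg.transitions[state])
        stim = _stimulus_at(odor_intervals, times[min(t_idx, n - 1)])
        if stim == "ACV" and "walking" in probs:
            probs["walking"] *= cfg.acv_walk_multiplier
        elif stim == "MSC" and "walking" in probs:
            probs["walking"] *= cfg.msc_walk_multiplier
        names = list(probs)
        p = np.array([probs[k] for k in names])
        state = names[rng.choice(len(names), p=p / p.sum())]

    walking = labels == "walking"

    # --- treadmill kinematics -------------------------------------------
    forward = np.zeros(n)
    yaw = np.zeros(n)
    # per walking bout: bout-specific base speed with smooth modulation and
    # short cosine ramps at the edges so the filtered velocity crosses the
    # 0.5 mm/s threshold close to the labeled boundary
    runs = []
    idx = np.flatnonzero(walking)
    if idx.size:
        splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        runs = [(int(s[0]), int(s[-1]) + 1) for s in splits]
    ramp_frames = int(0.15 * fs)
    for s, e in runs:
        stim = _stimulus_at(odor_intervals, times[s])
        base = max(2.0, rng.normal(cfg.forward_speed_mean, cfg.forward_speed_std))
        if stim == "ACV":
            base *= cfg.acv_speed_multiplier
        prof = base + _smooth_noise(rng, e - s, 0.15 * base)
        prof = np.clip(prof, 1.5, None)
        m = min(ramp_frames, (e - s) // 2)
        if m > 0:
            ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(m) / m))
            prof[:m] *= ramp
            prof[e - s - m :] *= ramp[::-1]
        forward[s:e] = prof
        # turn bouts inside the walking run
        n_bouts = rng.poisson(cfg.turn_rate_hz * (e - s) / fs)
        for _ in range(n_bouts):
            dur = rng.uniform(*cfg.turn_duration)
            w = int(dur * fs)
            if w >= e - s:
                continue
            off = int(rng.integers(0, e - s - w))
            amp = rng.normal(cfg.turn_amplitude, 0.4) * rng.choice([-1.0, 1.0])
            if stim == "ACV":
                amp *= cfg.acv_turn_multiplier
            yaw[s + off : s + off + w] += amp * _raised_cosine(w)
    forward += rng.normal(0.0, 0.03, n)
    forward[~walking] = np.clip(forward[~walking], -0.2, 0.2)
    yaw += gaussian_filter1d(rng.standard_normal(n), 10.0) * 0.05
    roll = gaussian_filter1d(rng.standard_normal(n), 10.0) * 0.05
    ball = BallRotationSeries(forward=forward, yaw=yaw, roll=roll, frame_times=times.copy())

    # --- pose proxy ------------------------------------------------------
    # 4 tracked joints (2 front-leg, 2 hindleg) x 3 axes; the first axis of
    # each joint oscillates when the corresponding legs move.  Amplitude is
    # calibrated so filtered per-set motion energy sits well above the 0.2
    # threshold during movement and below 0.3 at rest.
    front_active = np.isin(labels, ("walking", "head_grooming", "front_leg_rubbing"))
    hind_active = np.isin(labels, ("walking", "posterior_movements"))
    front_gate = gaussian_filter1d(front_active.astype(float), 3.0)
    hind_gate = gaussian_filter1d(hind_active.astype(float), 3.0)
    joints = rng.normal(0.0, 0.005, size=(4, 3, n))
    osc_f = 2.5
    phase = 2.0 * np.pi * osc_f * times
    for j, (gate, ph) in enumerate(
        [(front_gate, 0.0), (front_gate, 1.1), (hind_gate, 2.3), (hind_gate, 3.1)]
    ):
        joints[j, 0] += 2.0 * gate * np.sin(phase + ph)
    grooming = labels == "head_grooming"
    tarsus = np.where(grooming, 0.15, 0.01) + rng.normal(0.0, 0.004, n)
    tarsus = gaussian_filter1d(tarsus, 2.0)
    pose = PoseSeries(
        joint_positions=joints,
        frame_times=times.copy(),
        front_joints=[0, 1],
        hind_joints=[2, 3],
        front_tarsus_height=tarsus,
    )
    return labels, ball, pose, odor_intervals


def plant_ground_truth(cfg: GeneratorConfig, rng: np.random.Generator) -> list[GroundTruthNeuron]:
    """Assign encoding classes, weights, noise and ROI positions."""
    lo, hi = cfg.n_neurons_range
    n = int(rng.integers(lo, hi + 1))
    classes: list[str] = []
    for cls, prop in cfg.class_proportions.items():
        classes += [cls] * int(round(prop * n))
    classes += ["odor_acv"] * cfg.n_odor_neurons + ["odor_msc"] * cfg.n_odor_neurons
    if len(classes) > n:
        classes = classes[:n]
    classes += ["none"] * (n - len(classes))
    order = rng.permutation(n)
    neurons = []
    for nid in range(n):
        cls = classes[order[nid]]
        weights = {}
        if cls != "none":
            amp = cfg.amplitudes[cls] * rng.uniform(0.8, 1.2)
            weights[CLASS_REGRESSOR[cls]] = amp
        (mx, mz), (sx, sz) = cfg.roi_distributions[cls]
        x = float(np.clip(rng.normal(mx, sx), -41.0, 41.0))
        z = float(np.clip(rng.normal(mz, sz), 0.0, 60.0))
        neurons.append(
            GroundTruthNeuron(
                neuron_id=nid,
                encoding_class=cls,
                weights=weights,
                noise_sigma=cfg.noise_sigma,
                x=x,
                z=z,
            )
        )
    return neurons


def simulate_neural_traces(
    labels: np.ndarray,
    ball: BallRotationSeries,
    odor_intervals: list,
    truths: list[GroundTruthNeuron],
    kernel: CRFKernel,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    trial_index: int = 0,
) -> TraceMatrix:
    """Generate one trial's %ΔF/F matrix from the planted weights.

    Per neuron: drive(t) = sum_r w_r * regressor_r(t) at 100 Hz, convolved
    with the crf, resampled to neural frames, plus white Gaussian noise.
    """
    times = ball.frame_times
    neural_times = cfg.neural_times()
    regs = build_regressors(labels, ball, odor_intervals, times)
    n_neurons = len(truths)
    drives = np.zeros((n_neurons, times.size))
    for i, gt in enumerate(truths):
        for name, w in gt.weights.items():
            if name not in regs:
                raise KeyError(f"ground-truth weight references unknown regressor {name!r}")
            drives[i] += w * regs[name]
    conv = convolve_with_crf(drives, kernel)
    values = resample_to_neural(conv, times, neural_times)
    sig = np.array([gt.noise_sigma for gt in truths])
    values = values + rng.standard_normal(values.shape) * sig[:, None]
    if cfg.photobleach_drift:
        values = values - cfg.photobleach_drift * (trial_index + neural_times / cfg.trial_duration)[None, :]
    return TraceMatrix(
        values=values,
        frame_times=neural_times,
        neuron_ids=np.arange(n_neurons),
        trial_id=str(trial_index),
    )


def simulate_fly(cfg: GeneratorConfig, fly_id: int, seed_seq: np.random.SeedSequence) -> FlyRecording:
    gt_seq, *trial_seqs = seed_seq.spawn(cfg.n_trials + 1)
    rng = np.random.default_rng(gt_seq)
    truths = plant_ground_truth(cfg, rng)
    roi = np.array([[gt.x, gt.z] for gt in truths])
    kernel = cfg.kernel()
    trials = []
    for t_idx, ts in enumerate(trial_seqs):
        trng = np.random.default_rng(ts)
        labels, ball, pose, odors = simulate_behavior_and_stimuli(cfg, trng)
        traces = simulate_neural_traces(
            labels, ball, odors, truths, kernel, cfg, trng, trial_index=t_idx
        )
        trials.append(
            TrialRecording(
                fly_id=fly_id,
                trial_id=t_idx,
                traces=traces,
                labels=labels,
                label_times=ball.frame_times,
                ball=ball,
                pose=pose,
                odor_intervals=odors,
                roi_positions=roi,
            )
        )
    return FlyRecording(fly_id=fly_id, ground_truth=truths, trials=trials)


def generate_experiment(cfg: GeneratorConfig) -> Experiment:
    """Generate the full multi-fly experiment (deterministic in cfg.seed)."""
    root = np.random.SeedSequence(cfg.seed)
    fly_seqs = root.spawn(cfg.n_flies)
    flies = [simulate_fly(cfg, i, fs) for i, fs in enumerate(fly_seqs)]
    return Experiment(config=cfg, flies=flies)
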