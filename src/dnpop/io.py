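"""On-disk experiment layout.

One experiment directory holds a YAML config, an optional ground-truth CSV
(synthetic experiments), and per fly/trial subdirectories::

    root/
      config.yaml
      ground_truth.csv          # synthetic experiments only
      fly_000/trial_000/
        neural.h5               # dff (neuron x frame), frame_times, roi_positions
        behavior.csv            # frame_time, label
        ball.csv                # frame_time, forward, yaw, roll
        odor.csv                # start, end, stimulus
        pose.csv                # optional: frame_time, tarsus height, joint coords

Dense matrices use HDF5 (written without timestamps so identical data give
byte-identical files); labels, events and schedules use CSV.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .behavior import BallRotationSeries, PoseSeries
from .signals import TraceMatrix
from .simulate import Experiment, FlyRecording, GeneratorConfig, GroundTruthNeuron, TrialRecording

__all__ = [
    "write_experiment",
    "read_experiment",
    "write_pose_csv",
    "read_pose_csv",
    "write_ball_csv",
    "read_ball_csv",
    "write_labels_csv",
    "read_labels_csv",
]


def _write_h5(path: Path, arrays: dict[str, np.ndarray]) -> None:
    with h5py.File(path, "w", track_order=True) as f:
        for name, arr in arrays.items():
            f.create_dataset(name, data=arr, track_times=False)


def write_labels_csv(path: Path, times: np.ndarray, labels: np.ndarray) -> None:
    pd.DataFrame({"frame_time": times, "label": labels}).to_csv(path, index=False)


def read_labels_csv(path: Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df["frame_time"].to_numpy(), df["label"].to_numpy(dtype="U20")


def write_ball_csv(path: Path, ball: BallRotationSeries) -> None:
    pd.DataFrame(
        {
            "frame_time": ball.frame_times,
            "forward": ball.forward,
            "yaw": ball.yaw,
            "roll": ball.roll,
        }
    ).to_csv(path, index=False)


def read_ball_csv(path: Path) -> BallRotationSeries:
    df = pd.read_csv(path)
    return BallRotationSeries(
        forward=df["forward"].to_numpy(),
        yaw=df["yaw"].to_numpy(),
        roll=df["roll"].to_numpy(),
        frame_times=df["frame_time"].to_numpy(),
    )


def write_pose_csv(path: Path, pose: PoseSeries) -> None:
    cols = {"frame_time": pose.frame_times, "front_tarsus_height": pose.front_tarsus_height}
    n_joints = pose.joint_positions.shape[0]
    for j in range(n_joints):
        side = "front" if j in pose.front_joints else "hind"
        for a, ax in enumerate("xyz"):
            cols[f"joint{j}_{side}_{ax}"] = pose.joint_positions[j, a]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_pose_csv(path: Path) -> PoseSeries:
    df = pd.read_csv(path)
    joint_cols = [c for c in df.columns if c.startswith("joint")]
    n_joints = len({c.split("_")[0] for c in joint_cols})
    pos = np.empty((n_joints, 3, len(df)))
    front, hind = [], []
    for c in joint_cols:
        name, side, ax = c.split("_")
        j = int(name.removeprefix("joint"))
        pos[j, "xyz".index(ax)] = df[c].to_numpy()
        (front if side == "front" else hind).append(j)
    return PoseSeries(
        joint_positions=pos,
        frame_times=df["frame_time"].to_numpy(),
        front_joints=sorted(set(front)),
        hind_joints=sorted(set(hind)),
        front_tarsus_height=df["front_tarsus_height"].to_numpy(),
    )


def write_experiment(exp: Experiment, root: Path, write_pose: bool = True) -> Path:
    """Write an experiment to the on-disk layout; returns the root path."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    cfg = dataclasses.asdict(exp.config)
    cfg["n_neurons_range"] = list(cfg["n_neurons_range"])
    cfg["turn_duration"] = list(cfg["turn_duration"])
    with open(root / "config.yaml", "w") as f:
        yaml.safe_dump(cfg, f, sort_keys=True)
    exp.ground_truth_frame().to_csv(root / "ground_truth.csv", index=False)
    for fly in exp.flies:
        for tr in fly.trials:
            d = root / f"fly_{fly.fly_id:03d}" / f"trial_{tr.trial_id:03d}"
            d.mkdir(parents=True, exist_ok=True)
            _write_h5(
                d / "neural.h5",
                {
                    "dff": tr.traces.values,
                    "frame_times": tr.traces.frame_times,
                    "roi_positions": tr.roi_positions,
                },
            )
            write_labels_csv(d / "behavior.csv", tr.label_times, tr.labels)
            write_ball_csv(d / "ball.csv", tr.ball)
            pd.DataFrame(tr.odor_intervals, columns=["start", "end", "stimulus"]).to_csv(
                d / "odor.csv", index=False
            )
            if write_pose:
                write_pose_csv(d / "pose.csv", tr.pose)
    return root


def read_experiment(root: Path) -> Experiment:
    """Read an experiment directory back into memory.

    Missing optional files (pose, ground truth) are tolerated; a missing
    required file raises FileNotFoundError naming the trial.
    """
    root = Path(root)
    with open(root / "config.yaml") as f:
        raw = yaml.safe_load(f)
    cfg = GeneratorConfig.from_dict(raw)
    gt_path = root / "ground_truth.csv"
    gt_all = pd.read_csv(gt_path) if gt_path.exists() else None
    flies = []
    for fly_dir in sorted(root.glob("fly_*")):
        fly_id = int(fly_dir.name.split("_")[1])
        trials = []
        for trial_dir in sorted(fly_dir.glob("trial_*")):
            trial_id = int(trial_dir.name.split("_")[1])
            h5_path = trial_dir / "neural.h5"
            if not h5_path.exists():
                raise FileNotFoundError(f"{trial_dir}: neural.h5 missing")
            with h5py.File(h5_path, "r") as f:
                dff = f["dff"][()]
                frame_times = f["frame_times"][()]
                roi = f["roi_positions"][()]
            times, labels = read_labels_csv(trial_dir / "behavior.csv")
            ball = read_ball_csv(trial_dir / "ball.csv")
            odor = [
                (row.start, row.end, row.stimulus)
                for row in pd.read_csv(trial_dir / "odor.csv").itertuples()
            ]
            pose_path = trial_dir / "pose.csv"
            pose = read_pose_csv(pose_path) if pose_path.exists() else None
            trials.append(
                TrialRecording(
                    fly_id=fly_id,
                    trial_id=trial_id,
                    traces=TraceMatrix(
                        values=dff,
                        frame_times=frame_times,
                        neuron_ids=np.arange(dff.shape[0]),
                        trial_id=str(trial_id),
                    ),
                    labels=labels,
                    label_times=times,
                    ball=ball,
                    pose=pose,
                    odor_intervals=odor,
                    roi_positions=roi,
                )
            )
        truths = []
        if gt_all is not None:
            sub = gt_all[gt_all.fly_id == fly_id]
            wcols = [c for c in sub.columns if c.startswith("w_")]
            for row in sub.itertuples():
                weights = {
                    c.removeprefix("w_"): getattr(row, c)
                    for c in wcols
                    if getattr(row, c) != 0.0
                }
                truths.append(
                    GroundTruthNeuron(
                        neuron_id=int(row.neuron_id),
                        encoding_class=row.encoding_class,
                        weights=weights,
                        noise_sigma=float(row.noise_sigma),
                        x=float(row.x),
                        z=float(row.z),
                    )
                )
        flies.append(FlyRecording(fly_id=fly_id, ground_truth=truths, trials=trials))
    return Experiment(config=cfg, flies=flies)
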