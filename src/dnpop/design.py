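"""Regressor construction: from labels, treadmill rotations and odor
schedules to crf-convolved design matrices on the neural frame grid.

Regressors are built at the 100 Hz behavior rate, convolved with the crf
there (convolve-then-resample), and linearly interpolated at the neural
frame times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .behavior import BEHAVIOR_STATES, BallRotationSeries
from .signals import CRFKernel, convolve_with_crf, resample_to_neural

__all__ = [
    "DesignMatrix",
    "behavior_indicators",
    "odor_indicator",
    "rotation_channels",
    "build_regressors",
    "convolved_design",
]


@dataclass
class DesignMatrix:
    """Frame x regressor matrix at neural frame times.

    The intercept is handled by the fit (centering), not stored as a column.
    ``groups`` maps a tag (behavior / rotation / odor / custom) to the list
    of column names it covers; ``trial_ids`` assigns each row to a trial so
    that cross-validation folds and shuffles stay within trials.
    """

    names: list[str]
    values: np.ndarray
    trial_ids: np.ndarray
    groups: dict[str, list[str]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.names):
            raise ValueError("values must be frame x regressor")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("design matrix contains non-finite values")
        if self.trial_ids.shape[0] != self.values.shape[0]:
            raise ValueError("one trial id per row required")

    def columns(self, names: list[str]) -> np.ndarray:
        idx = [self.names.index(n) for n in names]
        return np.asarray(idx, dtype=int)


def behavior_indicators(
    labels: np.ndarray, states: tuple[str, ...] = BEHAVIOR_STATES
) -> dict[str, np.ndarray]:
    """Binary per-frame indicator series, one per behavior state."""
    return {s: (labels == s).astype(float) for s in states}


def odor_indicator(intervals: list[tuple[float, float, str]], times: np.ndarray, stimulus: str) -> np.ndarray:
    """Binary indicator of a stimulus from an (start, end, name) schedule."""
    out = np.zeros(times.size)
    for start, end, name in intervals:
        if name == stimulus:
            out[(times >= start) & (times < end)] = 1.0
    return out


def rotation_channels(ball: BallRotationSeries) -> dict[str, np.ndarray]:
    """Forward speed plus rectified yaw split into right/left turning.

    Positive yaw is a right turn, so ``yaw_right`` is the positive part of
    yaw and ``yaw_left`` the positive part of its negation.
    """
    return {
        "forward": ball.forward.copy(),
        "yaw_right": np.clip(ball.yaw, 0.0, None),
        "yaw_left": np.clip(-ball.yaw, 0.0, None),
    }


def build_regressors(
    labels: np.ndarray,
    ball: BallRotationSeries,
    odor_intervals: list[tuple[float, float, str]],
    times: np.ndarray,
    odors: tuple[str, ...] = ("ACV", "MSC"),
) -> dict[str, np.ndarray]:
    """All raw (unconvolved) regressor series on the 100 Hz grid."""
    regs = behavior_indicators(labels)
    regs.update(rotation_channels(ball))
    for odor in odors:
        regs[f"odor_{odor.lower()}"] = odor_indicator(odor_intervals, times, odor)
    return regs


def convolved_design(
    regressors: dict[str, np.ndarray],
    behavior_times: np.ndarray,
    neural_times: np.ndarray,
    kernel: CRFKernel,
    trial_id: object = 0,
    groups: dict[str, list[str]] | None = None,
) -> DesignMatrix:
    """Convolve each regressor with the crf and resample to neural frames."""
    names = list(regressors)
    stacked = np.vstack([regressors[n] for n in names])
    conv = convolve_with_crf(stacked, kernel)
    resampled = resample_to_neural(conv, behavior_times, neural_times)
    if groups is None:
        groups = {
            "behavior": [n for n in names if n in BEHAVIOR_STATES],
            "rotation": [n for n in names if n in ("forward", "yaw_right", "yaw_left")],
            "odor": [n for n in names if n.startswith("odor_")],
        }
    return DesignMatrix(
        names=names,
        values=resampled.T,
        trial_ids=np.full(neural_times.size, trial_id, dtype=object),
        groups=groups,
    )


def concat_designs(designs: list[DesignMatrix]) -> DesignMatrix:
    """Stack per-trial design matrices along the frame axis."""
    names = designs[0].names
    if any(d.names != names for d in designs):
        raise ValueError("designs must share regressor names")
    return DesignMatrix(
        names=names,
        values=np.vstack([d.values for d in designs]),
        trial_ids=np.concatenate([d.trial_ids for d in designs]),
        groups=designs[0].groups,
    )
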