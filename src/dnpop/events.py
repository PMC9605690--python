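"""Behavior-event extraction, event-triggered averaging, correlation
analyses, and Ward clustering of the neuron correlation matrix.

An "event" is one epoch of a behavior.  Event-triggered averages align
signal blocks spanning 1 s before onset to at most 4 s after (or the epoch
end, whichever is shorter); onsets with another epoch of the same behavior
in the preceding second are excluded.  Pixel-array averages re-baseline
each block by the mean of its first five frames and are discarded when
fewer than 50 events survive 1 s after onset; trace averages use ΔF/F
directly without block-wise re-baselining.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "Event",
    "extract_isolated_events",
    "event_triggered_average",
    "correlation_analysis",
    "lagged_correlation",
    "ward_ordering",
]

MIN_EVENTS_PIXEL = 50


@dataclass
class Event:
    behavior: str
    onset: float
    end: float
    trial_id: object

    @property
    def block(self) -> tuple[float, float]:
        return (self.onset - 1.0, min(self.onset + 4.0, self.end))


def extract_isolated_events(
    labels: np.ndarray,
    times: np.ndarray,
    behavior: str,
    trial_id: object = 0,
    isolation: float = 1.0,
    pre: float = 1.0,
    post_max: float = 4.0,
) -> list[Event]:
    """Epochs of a behavior with no same-behavior epoch in the prior 1 s.

    An onset is excluded when any frame of the preceding ``isolation``
    seconds carries the same behavior label (i.e., the previous epoch's
    offset falls inside the isolation window).  Onsets earlier than ``pre``
    seconds into the series are excluded so the full pre-window exists.
    """
    idx = np.flatnonzero(np.asarray(labels) == behavior)
    if idx.size == 0:
        return []
    splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    dt = float(np.median(np.diff(times)))
    events = []
    prev_end_time = -np.inf
    for s in splits:
        onset = float(times[s[0]])
        end = float(times[s[-1]]) + dt
        if onset - prev_end_time > isolation and onset >= times[0] + pre:
            events.append(
                Event(behavior=behavior, onset=onset, end=end, trial_id=trial_id)
            )
        prev_end_time = end
    return events


def event_triggered_average(
    signal: np.ndarray,
    times: np.ndarray,
    events: list[Event],
    mode: str = "trace",
    pre: float = 1.0,
    post_max: float = 4.0,
    min_events_at_1s: int = MIN_EVENTS_PIXEL,
) -> dict:
    """Align signal blocks at event onsets and average per time point.

    ``signal`` is (channels, frames) — ROI traces or flattened pixels.
    In ``pixel`` mode each block is re-baselined by the mean of its first
    five frames (ΔF/F relative to the pre-onset window) and the output is
    flagged ``discarded`` when fewer than ``min_events_at_1s`` blocks reach
    1 s after onset.  In ``trace`` mode values are used as is.
    """
    if mode not in ("trace", "pixel"):
        raise ValueError("mode must be 'trace' or 'pixel'")
    if not events:
        raise ValueError("no events to average")
    sig = np.atleast_2d(np.asarray(signal, dtype=float))
    dt = float(np.median(np.diff(times)))
    n_pre = int(round(pre / dt))
    n_post = int(round(post_max / dt))
    width = n_pre + n_post  # half-open window [onset - pre, onset + post_max)
    acc = np.zeros((sig.shape[0], width))
    count = np.zeros(width)
    for ev in events:
        onset_idx = int(np.searchsorted(times, ev.onset))
        stop_time = min(ev.onset + post_max, ev.end)
        stop_idx = min(int(np.searchsorted(times, stop_time)), sig.shape[1])
        lo = onset_idx - n_pre
        if lo < 0 or stop_idx <= onset_idx:
            warnings.warn("event block exceeds signal bounds; trimmed")
            lo = max(lo, 0)
        block = sig[:, lo:stop_idx]
        if mode == "pixel":
            if block.shape[1] < 5:
                continue
            block = block - block[:, :5].mean(axis=1, keepdims=True)
        k = block.shape[1]
        offset = n_pre - (onset_idx - lo)
        acc[:, offset : offset + k] += block
        count[offset : offset + k] += 1
    with np.errstate(invalid="ignore"):
        mean = acc / count[None, :]
    t_rel = (np.arange(width) - n_pre) * dt
    out = {
        "time": t_rel,
        "mean": mean,
        "n": count.astype(int),
        "discarded": False,
    }
    if mode == "pixel":
        at_1s = int(count[int(np.searchsorted(t_rel, 1.0 - 1e-9))])
        if at_1s < min_events_at_1s:
            out["discarded"] = True
    return out


def lagged_correlation(x: np.ndarray, y: np.ndarray, max_lag: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Pearson r of x against y shifted by each integer lag.

    Positive lag means y is delayed relative to x.  Returns (lags, r,
    argmax lag).
    """
    lags = np.arange(-max_lag, max_lag + 1)
    rs = np.empty(lags.size)
    for i, lag in enumerate(lags):
        if lag >= 0:
            a, b = x[: x.size - lag or None], y[lag:]
        else:
            a, b = x[-lag:], y[: y.size + lag]
        rs[i] = np.corrcoef(a, b)[0, 1]
    return lags, rs, int(lags[int(np.nanargmax(rs))])


def correlation_analysis(
    trial_traces: list[np.ndarray],
    trial_balls=None,
    trial_labels=None,
) -> dict:
    """Trial-averaged Pearson correlation structure of a population.

    Pairwise neuron correlations use all frames of each trial; correlations
    between neurons and turning (rectified right/left yaw) or forward speed
    use walking frames only.  All values are computed per trial and then
    averaged across trials; constant traces yield masked (NaN) entries.
    """
    mats = []
    for tr in trial_traces:
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.corrcoef(tr)
        mats.append(c)
    if len(mats) < 2:
        warnings.warn("single trial: correlation matrix is not trial-averaged")
    corr = np.nanmean(np.stack(mats), axis=0)
    out = {"neuron_corr": corr}
    if trial_balls is not None and trial_labels is not None:
        aux = {"turn_right": [], "turn_left": [], "forward": []}
        for tr, ball_chans, labels in zip(trial_traces, trial_balls, trial_labels):
            walk = labels == "walking"
            if walk.sum() < 10:
                continue
            for name in aux:
                v = ball_chans[name][walk]
                with np.errstate(invalid="ignore", divide="ignore"):
                    r = [np.corrcoef(row[walk], v)[0, 1] for row in tr]
                aux[name].append(r)
        out["kinematic_corr"] = pd.DataFrame(
            {k: np.nanmean(np.array(v), axis=0) for k, v in aux.items() if v}
        )
    return out


def ward_ordering(corr: np.ndarray) -> dict:
    """Ward linkage on the 1 - r distance and its deterministic leaf order.

    Masked (NaN) entries are imputed as distance 1 (zero correlation) with
    a warning.  Returns the linkage matrix and the leaf ordering.
    """
    corr = np.asarray(corr, dtype=float)
    dist = 1.0 - corr
    if np.isnan(dist).any():
        warnings.warn("masked correlation entries imputed as distance 1")
        dist = np.where(np.isnan(dist), 1.0, dist)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    condensed = squareform(dist, checks=False)
    link = hierarchy.linkage(condensed, method="ward")
    leaves = hierarchy.leaves_list(link)
    return {"linkage": link, "leaf_order": leaves}
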