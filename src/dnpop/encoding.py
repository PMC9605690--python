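"""Behavior/rotation/odor encoding analyses for neural populations.

The central object is a :class:`FlySession`: one fly's trials concatenated,
with %ΔF/F traces, a crf-convolved design matrix of behavior indicators,
rectified treadmill rotations and odor indicators, and per-neural-frame
behavior labels.  On top of it this module implements

* the behavior-encoding map: per (neuron, behavior), the cross-validated
  R^2 of predicting the crf-convolved behavior indicator from that single
  neuron's ΔF/F, with assignment to the best-explained behavior when the
  maximum R^2 reaches 5%;
* disambiguation of sequentially occurring behavior pairs by UEV on
  equal-sized frame subsets restricted to the two behaviors;
* turn/speed encoding, both population-level (all neurons predict convolved
  yaw or forward speed; UEV of the neural block by shuffling neurons) and
  per neuron against rectified right/left turning and forward speed, with
  an optional walking-only frame restriction;
* joint-angle UEV against behavior regressors and angle subgroups;
* odor UEV per neuron and odor-context-dependent behavior encoding with
  Mann-Whitney U tests over per-trial cross-validation folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .behavior import BEHAVIOR_STATES
from .design import DesignMatrix, build_regressors, concat_designs, convolved_design
from .regression import (
    CVConfig,
    CVResult,
    batch_cv_r2_multi,
    batch_cv_r2_single,
    batch_uev_multi,
    batch_uev_single,
    cross_validated_r2,
    shuffle_within_trials,
    unique_explained_variance,
)
from .signals import CRFKernel, make_crf_kernel

__all__ = [
    "FlySession",
    "assemble_session",
    "neuron_behavior_encoding_map",
    "assign_behaviors",
    "disambiguate_sequential_behaviors",
    "rotation_encoding",
    "joint_angle_uev",
    "odor_uev",
    "context_dependent_encoding",
]

ASSIGNMENT_CUTOFF = 0.05  # max R^2 below 5%: no behavior assigned


def nearest_labels(labels: np.ndarray, label_times: np.ndarray, neural_times: np.ndarray) -> np.ndarray:
    """Behavior label at each neural frame (nearest behavior frame)."""
    idx = np.clip(
        np.searchsorted(label_times, neural_times - 0.5 * np.median(np.diff(label_times))),
        0,
        labels.size - 1,
    )
    return labels[idx]


@dataclass
class FlySession:
    """One fly's trials, aligned and concatenated on the neural frame grid."""

    fly_id: object
    traces: np.ndarray  # neuron x frame, %ΔF/F
    neuron_ids: np.ndarray
    design: DesignMatrix  # crf-convolved regressors, same frames
    labels: np.ndarray  # behavior label per neural frame
    trial_ids: np.ndarray
    times: np.ndarray  # within-trial neural frame times

    @property
    def n_neurons(self) -> int:
        return self.traces.shape[0]

    def odor_mask(self, stimulus: str) -> np.ndarray:
        """Frames during which a stimulus was present (unconvolved schedule)."""
        return self.raw_odor[stimulus]

    raw_odor: dict | None = None


def assemble_session(trials, kernel: CRFKernel | None = None, fly_id=None) -> FlySession:
    """Concatenate a fly's :class:`~dnpop.simulate.TrialRecording` list."""
    if kernel is None:
        kernel = make_crf_kernel(dt=1.0 / round(1.0 / np.median(np.diff(trials[0].label_times)), 6))
    designs = []
    labels = []
    raw_odor: dict[str, list[np.ndarray]] = {"air": [], "ACV": [], "MSC": []}
    for tr in trials:
        regs = build_regressors(tr.labels, tr.ball, tr.odor_intervals, tr.label_times)
        designs.append(
            convolved_design(regs, tr.label_times, tr.traces.frame_times, kernel, trial_id=tr.trial_id)
        )
        labels.append(nearest_labels(tr.labels, tr.label_times, tr.traces.frame_times))
        for stim in raw_odor:
            ind = np.zeros(tr.traces.frame_times.size, dtype=bool)
            for start, end, name in tr.odor_intervals:
                if name == stim:
                    ind |= (tr.traces.frame_times >= start) & (tr.traces.frame_times < end)
            raw_odor[stim].append(ind)
    session = FlySession(
        fly_id=trials[0].fly_id if fly_id is None else fly_id,
        traces=np.hstack([tr.traces.values for tr in trials]),
        neuron_ids=trials[0].traces.neuron_ids,
        design=concat_designs(designs),
        labels=np.concatenate(labels),
        trial_ids=np.concatenate(
            [np.full(tr.traces.n_frames, tr.trial_id, dtype=object) for tr in trials]
        ),
        times=np.concatenate([tr.traces.frame_times for tr in trials]),
    )
    session.raw_odor = {k: np.concatenate(v) for k, v in raw_odor.items()}
    return session


def neuron_behavior_encoding_map(
    session: FlySession,
    cv: CVConfig = CVConfig(),
    behaviors: tuple[str, ...] = BEHAVIOR_STATES,
) -> pd.DataFrame:
    """Cross-validated R^2 of every (neuron, behavior) single-neuron model.

    The target is the crf-convolved binary behavior indicator; the model's
    single regressor (besides the intercept) is one neuron's ΔF/F.
    Behaviors never expressed by the fly are omitted.
    """
    rows = []
    Xn = session.traces.T  # frames x neurons; each column its own model
    for beh in behaviors:
        col = session.design.values[:, session.design.names.index(beh)]
        if float(col.max()) <= 0.0:
            warnings.warn(f"behavior {beh!r} never occurs; omitted from the map")
            continue
        res = batch_cv_r2_single(Xn, col, session.trial_ids, cv)
        for i, nid in enumerate(session.neuron_ids):
            fr = res.fold_r2[:, i]
            rows.append(
                {
                    "fly_id": session.fly_id,
                    "neuron_id": nid,
                    "behavior": beh,
                    "r2": float(res.r2[i]),
                    "r2_raw": float(np.nanmean(fr)),
                    "n_folds": int(np.isfinite(fr).sum()),
                }
            )
    return pd.DataFrame(rows)


def assign_behaviors(
    encoding_map: pd.DataFrame, cutoff: float = ASSIGNMENT_CUTOFF
) -> pd.DataFrame:
    """Assign each neuron the behavior with maximum R^2 (cutoff rule).

    Neurons whose maximum R^2 is below ``cutoff`` get assignment "none".
    Exact ties break toward the earlier behavior in the canonical order.
    """
    order = {b: i for i, b in enumerate(BEHAVIOR_STATES)}
    out = []
    for (fly, nid), grp in encoding_map.groupby(["fly_id", "neuron_id"], sort=False):
        grp = grp.sort_values("behavior", key=lambda s: s.map(order))
        best = grp.iloc[int(np.argmax(grp["r2"].to_numpy()))]
        out.append(
            {
                "fly_id": fly,
                "neuron_id": nid,
                "assigned": best["behavior"] if best["r2"] >= cutoff else "none",
                "max_r2": best["r2"],
            }
        )
    return pd.DataFrame(out)


def disambiguate_sequential_behaviors(
    session: FlySession,
    neuron: int,
    behavior_a: str,
    behavior_b: str,
    cv: CVConfig = CVConfig(),
) -> dict:
    """UEV of two sequential behaviors for one neuron, on balanced frames.

    Restricts to frames labeled either behavior, subsamples the commoner
    one (seeded) to equal counts, then fits a two-regressor model of the
    neuron's ΔF/F on the convolved indicators and computes each UEV.
    """
    rng = np.random.default_rng(cv.seed)
    lab = session.labels
    idx_a = np.flatnonzero(lab == behavior_a)
    idx_b = np.flatnonzero(lab == behavior_b)
    n = min(idx_a.size, idx_b.size)
    if n < cv.k_outer * 10:
        raise ValueError(
            f"insufficient data: {behavior_a}={idx_a.size}, {behavior_b}={idx_b.size} frames"
        )
    keep = np.sort(
        np.concatenate(
            [rng.choice(idx_a, n, replace=False), rng.choice(idx_b, n, replace=False)]
        )
    )
    cols = session.design.columns([behavior_a, behavior_b])
    X = session.design.values[np.ix_(keep, cols)]
    y = session.traces[neuron][keep]
    tid = session.trial_ids[keep]
    uev_a, intact = unique_explained_variance(X, y, [0], tid, cv)
    uev_b, _ = unique_explained_variance(X, y, [1], tid, cv, intact=intact)
    return {
        "neuron_id": int(session.neuron_ids[neuron]),
        "behavior_a": behavior_a,
        "behavior_b": behavior_b,
        "uev_a": uev_a,
        "uev_b": uev_b,
        "r2_intact": intact.r2,
        "n_frames_per_behavior": int(n),
    }


def _target_column(session: FlySession, name: str) -> np.ndarray:
    d = session.design
    if name == "turning":
        return (
            d.values[:, d.names.index("yaw_right")] - d.values[:, d.names.index("yaw_left")]
        )
    return d.values[:, d.names.index(name)]


def rotation_encoding(
    session: FlySession,
    cv: CVConfig = CVConfig(),
    walking_only: bool = False,
    per_neuron: bool = False,
) -> pd.DataFrame:
    """Turn/speed encoding from neural activity.

    Population mode: predict the crf-convolved yaw ("turning") and forward
    speed ("speed") from all behavior regressors plus all neurons' ΔF/F;
    the neural block's UEV is the drop in R^2 when all neuron columns are
    temporally shuffled.  Per-neuron mode: predict rectified right turning,
    left turning and forward speed from one neuron at a time.
    ``walking_only`` restricts all rows to walking-labeled frames.
    """
    mask = session.labels == "walking" if walking_only else np.ones(session.labels.size, bool)
    if mask.sum() < cv.k_outer * 20:
        raise ValueError("insufficient (walking) frames for rotation encoding")
    tid = session.trial_ids[mask]
    rows = []
    if per_neuron:
        targets = {
            "turn_right": _target_column(session, "yaw_right")[mask],
            "turn_left": _target_column(session, "yaw_left")[mask],
            "speed": _target_column(session, "forward")[mask],
        }
        rng = np.random.default_rng(cv.seed)
        Xn = session.traces[:, mask].T
        for tname, y in targets.items():
            uev, intact = batch_uev_single(
                Xn, y, tid, cv, rng=np.random.default_rng(rng.integers(2**31))
            )
            for i, nid in enumerate(session.neuron_ids):
                rows.append(
                    {
                        "fly_id": session.fly_id,
                        "neuron_id": nid,
                        "target": tname,
                        "r2": float(intact.r2[i]),
                        "uev": float(uev[i]),
                        "walking_only": walking_only,
                    }
                )
        return pd.DataFrame(rows)

    beh_cols = session.design.columns(session.design.groups["behavior"])
    X = np.column_stack(
        [session.design.values[np.ix_(np.flatnonzero(mask), beh_cols)], session.traces[:, mask].T]
    )
    neural_cols = np.arange(beh_cols.size, X.shape[1])
    for tname in ("turning", "speed"):
        y = _target_column(session, tname if tname == "turning" else "forward")[mask]
        uev, intact = unique_explained_variance(X, y, neural_cols, tid, cv)
        rows.append(
            {
                "fly_id": session.fly_id,
                "target": tname,
                "r2": intact.r2,
                "uev_neural": uev,
                "walking_only": walking_only,
            }
        )
    return pd.DataFrame(rows)


def joint_angle_uev(
    session: FlySession,
    neuron: int,
    angle_design: DesignMatrix,
    groups: dict[str, list[str]],
    cv: CVConfig = CVConfig(),
) -> dict:
    """UEV of joint-angle subgroups for one neuron.

    The full model holds all behavior regressors plus all (crf-convolved)
    joint-angle regressors; a group's UEV shuffles only that group's
    columns, leaving the remaining angles and the behaviors intact.
    """
    beh_cols = session.design.columns(session.design.groups["behavior"])
    X = np.column_stack(
        [session.design.values[:, beh_cols], angle_design.values]
    )
    names = [session.design.names[c] for c in beh_cols] + list(angle_design.names)
    y = session.traces[neuron]
    intact = cross_validated_r2(X, y, session.trial_ids, cv)
    out = {"r2_intact": intact.r2}
    rng = np.random.default_rng(cv.seed)
    for gname, members in groups.items():
        missing = [m for m in members if m not in names]
        if missing:
            raise KeyError(f"group {gname!r} references unknown angles {missing}")
        cols = [names.index(m) for m in members]
        uev, _ = unique_explained_variance(
            X, y, cols, session.trial_ids, cv, intact=intact,
            rng=np.random.default_rng(rng.integers(2**31)),
        )
        out[gname] = uev
    return out


def joint_angle_uev_population(
    session: FlySession,
    angle_design: DesignMatrix,
    groups: dict[str, list[str]],
    cv: CVConfig = CVConfig(),
) -> pd.DataFrame:
    """Joint-angle group UEVs for every neuron at once."""
    beh_cols = session.design.columns(session.design.groups["behavior"])
    X = np.column_stack([session.design.values[:, beh_cols], angle_design.values])
    names = [session.design.names[c] for c in beh_cols] + list(angle_design.names)
    Y = session.traces.T
    intact = batch_cv_r2_multi(X, Y, session.trial_ids, cv)
    out = pd.DataFrame(
        {"fly_id": session.fly_id, "neuron_id": session.neuron_ids, "r2_intact": intact.r2}
    )
    rng = np.random.default_rng(cv.seed)
    for gname, members in groups.items():
        missing = [m for m in members if m not in names]
        if missing:
            raise KeyError(f"group {gname!r} references unknown angles {missing}")
        cols = [names.index(m) for m in members]
        uev, _ = batch_uev_multi(
            X, Y, cols, session.trial_ids, cv, intact=intact,
            rng=np.random.default_rng(rng.integers(2**31)),
        )
        out[f"uev_{gname}"] = uev
    return out


def odor_uev(
    session: FlySession,
    neuron: int,
    cv: CVConfig = CVConfig(),
    odors: tuple[str, ...] = ("odor_acv", "odor_msc"),
) -> dict:
    """Odor encoding of one neuron beyond behavior and rotations.

    Fits the neuron's ΔF/F on behavior indicators, convolved rotations and
    odor regressors.  The behavior-composite R^2 shuffles both odor
    regressors at once; each odor's UEV shuffles only its own regressor.
    """
    d = session.design
    for o in odors:
        if d.values[:, d.names.index(o)].max() <= 0:
            raise ValueError(f"stimulus {o!r} never presented")
    names = d.groups["behavior"] + d.groups["rotation"] + list(odors)
    cols = d.columns(names)
    X = d.values[:, cols]
    y = session.traces[neuron]
    intact = cross_validated_r2(X, y, session.trial_ids, cv)
    odor_cols = [names.index(o) for o in odors]
    rng = np.random.default_rng(cv.seed)
    both_uev, _ = unique_explained_variance(
        X, y, odor_cols, session.trial_ids, cv, intact=intact,
        rng=np.random.default_rng(rng.integers(2**31)),
    )
    out = {
        "neuron_id": int(session.neuron_ids[neuron]),
        "r2_full": intact.r2,
        "r2_behavior": max(intact.r2 - both_uev, 0.0),
    }
    for o in odors:
        uev, _ = unique_explained_variance(
            X, y, [names.index(o)], session.trial_ids, cv, intact=intact,
            rng=np.random.default_rng(rng.integers(2**31)),
        )
        out[f"uev_{o.removeprefix('odor_')}"] = uev
    return out


def odor_uev_population(
    session: FlySession,
    cv: CVConfig = CVConfig(),
    odors: tuple[str, ...] = ("odor_acv", "odor_msc"),
) -> pd.DataFrame:
    """Odor UEV of every neuron at once (same model as :func:`odor_uev`)."""
    d = session.design
    for o in odors:
        if d.values[:, d.names.index(o)].max() <= 0:
            raise ValueError(f"stimulus {o!r} never presented")
    names = d.groups["behavior"] + d.groups["rotation"] + list(odors)
    X = d.values[:, d.columns(names)]
    Y = session.traces.T
    intact = batch_cv_r2_multi(X, Y, session.trial_ids, cv)
    rng = np.random.default_rng(cv.seed)
    odor_cols = [names.index(o) for o in odors]
    both_uev, _ = batch_uev_multi(
        X, Y, odor_cols, session.trial_ids, cv, intact=intact,
        rng=np.random.default_rng(rng.integers(2**31)),
    )
    out = pd.DataFrame(
        {
            "fly_id": session.fly_id,
            "neuron_id": session.neuron_ids,
            "r2_full": intact.r2,
            "r2_behavior": np.clip(intact.r2 - both_uev, 0.0, None),
        }
    )
    for o in odors:
        uev, _ = batch_uev_multi(
            X, Y, [names.index(o)], session.trial_ids, cv, intact=intact,
            rng=np.random.default_rng(rng.integers(2**31)),
        )
        out[f"uev_{o.removeprefix('odor_')}"] = uev
    return out


def _typical_block_length(mask: np.ndarray) -> int:
    """Median run length of True runs in a boolean mask."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return 1
    splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    return int(np.median([s.size for s in splits]))


def context_dependent_encoding(
    session: FlySession,
    neuron: int,
    behavior: str,
    cv: CVConfig = CVConfig(),
) -> dict:
    """Behavior-encoding R^2 of one neuron per odor context.

    Per context (humid air / ACV / MSC) the single-neuron behavior model is
    refit using only frames from that context, with the air frames
    subsampled (seeded) to the odor-context frame count.  Cross-validation
    runs per trial; the per-trial fold R^2 values are the data points of
    two-sided Mann-Whitney U tests between contexts.
    """
    rng = np.random.default_rng(cv.seed)
    beh_col = _target_column(session, behavior)

    def _blocks(mask: np.ndarray, in_trial: np.ndarray) -> list[np.ndarray]:
        idx = np.flatnonzero(mask & in_trial)
        if idx.size == 0:
            return []
        return np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)

    # Every context is reduced to the same number of equally long contiguous
    # presentation blocks per trial (seeded choice): air is subsampled to the
    # odor amount, and the commoner odor down to the rarer one, so the three
    # contexts have matched data amount and autocorrelation structure.
    acv_all = session.odor_mask("ACV")
    msc_all = session.odor_mask("MSC")
    air_all = session.odor_mask("air")
    block_len = _typical_block_length(acv_all | msc_all)
    masks = {k: np.zeros(beh_col.size, bool) for k in ("ACV", "MSC", "air")}
    for trial in pd.unique(session.trial_ids):
        in_trial = session.trial_ids == trial
        blocks = {"ACV": _blocks(acv_all, in_trial), "MSC": _blocks(msc_all, in_trial)}
        n_keep = min(len(blocks["ACV"]), len(blocks["MSC"]))
        if n_keep == 0:
            continue
        for ctx in ("ACV", "MSC"):
            chosen = rng.choice(len(blocks[ctx]), n_keep, replace=False)
            for b in sorted(chosen):
                masks[ctx][blocks[ctx][b]] = True
        air_idx = np.flatnonzero(air_all & in_trial)
        if air_idx.size <= block_len:
            masks["air"][air_idx] = True
            continue
        for _ in range(n_keep):
            start = int(rng.choice(air_idx[: air_idx.size - block_len]))
            sl = slice(start, start + block_len)
            masks["air"][sl] |= air_all[sl]

    fold_values: dict[str, list[float]] = {}
    means: dict[str, float] = {}
    for ctx, mask in masks.items():
        vals: list[float] = []
        for trial in pd.unique(session.trial_ids):
            sel = mask & (session.trial_ids == trial)
            if (session.labels[sel] == behavior).sum() < cv.k_outer * 2:
                warnings.warn(
                    f"context {ctx}, trial {trial}: behavior {behavior!r} too rare; excluded"
                )
                continue
            sel_idx = np.flatnonzero(sel)
            # each contiguous context block is a fold-building unit, so test
            # folds mix frames from several presentations
            block_ids = np.concatenate([[0], np.cumsum(np.diff(sel_idx) > 1)])
            counts = np.bincount(block_ids)
            block_ids = np.where(
                (counts < cv.k_outer)[block_ids], -1, block_ids
            )
            keep = block_ids >= 0
            try:
                res = cross_validated_r2(
                    session.traces[neuron][sel_idx[keep]],
                    beh_col[sel_idx[keep]],
                    block_ids[keep],
                    cv,
                )
            except (ZeroDivisionError, ValueError):
                continue
            vals.extend(res.fold_r2.tolist())
        fold_values[ctx] = vals
        means[ctx] = max(float(np.mean(vals)), 0.0) if vals else np.nan
    pvals = {}
    ctxs = list(masks)
    for i in range(len(ctxs)):
        for j in range(i + 1, len(ctxs)):
            a, b = fold_values[ctxs[i]], fold_values[ctxs[j]]
            if len(a) >= 2 and len(b) >= 2:
                pvals[f"{ctxs[i]}_vs_{ctxs[j]}"] = float(
                    mannwhitneyu(a, b, alternative="two-sided").pvalue
                )
            else:
                pvals[f"{ctxs[i]}_vs_{ctxs[j]}"] = np.nan
    return {
        "neuron_id": int(session.neuron_ids[neuron]),
        "behavior": behavior,
        "r2_per_context": means,
        "fold_values": fold_values,
        "p_values": pvals,
        "n_frames_air_subsampled": int(masks["air"].sum()),
    }
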