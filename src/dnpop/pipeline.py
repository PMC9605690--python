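"""End-to-end orchestration of the population encoding analysis.

``run_pipeline`` executes the analysis stages on an in-memory or on-disk
experiment and writes machine-readable tables (CSV), summaries (JSON) and a
log; ``recovery_report`` scores the pipeline outputs of a synthetic
experiment against its planted ground truth.

Stages (subset selectable): label, encoding, disambiguation, rotation,
joint_angles, odor, context, pca, decoding, spatial, events.
All randomness flows from one top-level seed; derived seeds are logged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import events as EV
from .behavior import (
    BEHAVIOR_STATES,
    HeuristicThresholds,
    compute_motion_energy,
    label_behavior_heuristic,
)
from .decoding import behavior_residuals, compare_feature_sets, residual_odor_classifier
from .density import normalized_density, select_bandwidth_loo
from .design import DesignMatrix, convolved_design
from .encoding import (
    FlySession,
    assemble_session,
    assign_behaviors,
    context_dependent_encoding,
    disambiguate_sequential_behaviors,
    joint_angle_uev_population,
    nearest_labels,
    neuron_behavior_encoding_map,
    odor_uev_population,
    rotation_encoding,
)
from .regression import CVConfig
from .simulate import Experiment
from .statespace import WalkingPCA

ALL_STAGES = (
    "label",
    "encoding",
    "disambiguation",
    "rotation",
    "joint_angles",
    "odor",
    "context",
    "pca",
    "decoding",
    "spatial",
    "events",
)

SEQUENTIAL_PAIRS = (
    ("head_grooming", "front_leg_rubbing"),
    ("walking", "posterior_movements"),
)

log = logging.getLogger("dnpop")


@dataclass
class PipelineResult:
    out_dir: Path
    tables: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)


def _df_to_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def run_pipeline(
    experiment: Experiment,
    out_dir: Path,
    stages: tuple[str, ...] | None = None,
    cv: CVConfig | None = None,
    seed: int = 0,
) -> PipelineResult:
    """Run the analysis stages on an experiment and write outputs.

    Unknown stage names raise; a stage whose inputs are missing (e.g. pose
    for the labeling stage) is skipped with a logged reason.  Rerunning
    with the same experiment, seed and stages rewrites identical outputs.
    """
    stages = tuple(stages) if stages else ALL_STAGES
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    if cv is None:
        cv = CVConfig(seed=seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result = PipelineResult(out_dir=out_dir)
    summary: dict = {"seed": seed, "stages": list(stages)}
    kernel = experiment.config.kernel()

    sessions = [assemble_session(fly.trials, kernel) for fly in experiment.flies]

    if "label" in stages:
        rows = []
        for fly, ses in zip(experiment.flies, sessions):
            for tr in fly.trials:
                if tr.pose is None:
                    log.info("label stage: fly %s trial %s has no pose; skipped", fly.fly_id, tr.trial_id)
                    continue
                me = compute_motion_energy(tr.pose)
                pred = label_behavior_heuristic(me, tr.ball, tr.pose)
                acc = float((pred == tr.labels).mean())
                rows.append({"fly_id": fly.fly_id, "trial_id": tr.trial_id, "frame_accuracy": acc})
        if rows:
            df = pd.DataFrame(rows)
            _df_to_csv(df, out_dir / "label_accuracy.csv")
            result.tables["label"] = df
            summary["label_mean_accuracy"] = float(df["frame_accuracy"].mean())

    assign_all = None
    if "encoding" in stages:
        maps, assigns = [], []
        for ses in sessions:
            emap = neuron_behavior_encoding_map(ses, cv)
            maps.append(emap)
            assigns.append(assign_behaviors(emap))
        emap_all = pd.concat(maps, ignore_index=True)
        assign_all = pd.concat(assigns, ignore_index=True)
        _df_to_csv(emap_all, out_dir / "encoding_map.csv")
        _df_to_csv(assign_all, out_dir / "encoding_assignment.csv")
        result.tables["encoding_map"] = emap_all
        result.tables["assignment"] = assign_all
        frac = (
            assign_all.groupby("assigned").size() / len(assign_all)
        ).to_dict()
        summary["population_fractions"] = {k: float(v) for k, v in frac.items()}

    if "disambiguation" in stages:
        rows = []
        for ses in sessions:
            for beh_a, beh_b in SEQUENTIAL_PAIRS:
                if assign_all is not None:
                    sel = assign_all[
                        (assign_all.fly_id == ses.fly_id)
                        & (assign_all.assigned.isin([beh_a, beh_b]))
                    ].neuron_id.tolist()
                else:
                    sel = list(ses.neuron_ids)
                for nid in sel:
                    i = int(np.flatnonzero(ses.neuron_ids == nid)[0])
                    try:
                        r = disambiguate_sequential_behaviors(ses, i, beh_a, beh_b, cv)
                    except ValueError as e:
                        log.info("disambiguation skipped (%s/%s, neuron %s): %s", beh_a, beh_b, nid, e)
                        continue
                    r["fly_id"] = ses.fly_id
                    rows.append(r)
        if rows:
            df = pd.DataFrame(rows)
            _df_to_csv(df, out_dir / "sequential_disambiguation.csv")
            result.tables["disambiguation"] = df

    if "rotation" in stages:
        pops, pers = [], []
        for ses in sessions:
            for walking_only in (False, True):
                try:
                    pops.append(rotation_encoding(ses, cv, walking_only=walking_only))
                except ValueError as e:
                    log.info("rotation population skipped (fly %s): %s", ses.fly_id, e)
            pers.append(rotation_encoding(ses, cv, walking_only=False, per_neuron=True))
        pop = pd.concat(pops, ignore_index=True)
        per = pd.concat(pers, ignore_index=True)
        _df_to_csv(pop, out_dir / "rotation_population.csv")
        _df_to_csv(per, out_dir / "rotation_per_neuron.csv")
        result.tables["rotation_population"] = pop
        result.tables["rotation_per_neuron"] = per
        wo = pop[pop.walking_only]
        summary["turning_uev_walking"] = float(
            wo[wo.target == "turning"].uev_neural.mean()
        )
        summary["speed_uev_walking"] = float(wo[wo.target == "speed"].uev_neural.mean())

    if "joint_angles" in stages:
        dfs = []
        for fly, ses in zip(experiment.flies, sessions):
            if any(tr.pose is None for tr in fly.trials):
                log.info("joint_angles: fly %s lacks pose; skipped", fly.fly_id)
                continue
            n_joints = fly.trials[0].pose.joint_positions.shape[0]
            per_trial = []
            for tr in fly.trials:
                regs = {}
                for j in range(n_joints):
                    side = "front" if j in tr.pose.front_joints else "hind"
                    regs[f"joint{j}_{side}"] = tr.pose.joint_positions[j, 0]
                per_trial.append(
                    convolved_design(
                        regs, tr.label_times, tr.traces.frame_times, kernel,
                        trial_id=tr.trial_id, groups={"angles": list(regs)},
                    )
                )
            from .design import concat_designs

            angle_design = concat_designs(per_trial)
            names = angle_design.names
            groups = {"all": list(names)}
            groups["front_pair"] = [n for n in names if "front" in n]
            groups["hind_pair"] = [n for n in names if "hind" in n]
            for n in names:
                groups[n] = [n]
            dfs.append(joint_angle_uev_population(ses, angle_design, groups, cv))
        if dfs:
            df = pd.concat(dfs, ignore_index=True)
            _df_to_csv(df, out_dir / "joint_angle_uev.csv")
            result.tables["joint_angles"] = df

    if "odor" in stages:
        dfs = [odor_uev_population(ses, cv) for ses in sessions]
        df = pd.concat(dfs, ignore_index=True)
        _df_to_csv(df, out_dir / "odor_uev.csv")
        result.tables["odor_uev"] = df
        summary["n_odor_encoding_neurons"] = int(
            ((df.uev_acv > 0.05) | (df.uev_msc > 0.05)).sum()
        )

    if "context" in stages:
        rows = []
        for ses in sessions:
            if assign_all is None:
                sel = []
                log.info("context: encoding stage not run; stage skipped")
                break
            sub = assign_all[
                (assign_all.fly_id == ses.fly_id)
                & (assign_all.assigned.isin(["walking", "head_grooming"]))
            ]
            for nid, beh in zip(sub.neuron_id, sub.assigned):
                i = int(np.flatnonzero(ses.neuron_ids == nid)[0])
                c = context_dependent_encoding(ses, i, beh, cv)
                rows.append(
                    {
                        "fly_id": ses.fly_id,
                        "neuron_id": nid,
                        "behavior": beh,
                        **{f"r2_{k.lower()}": v for k, v in c["r2_per_context"].items()},
                        **{f"p_{k.lower()}": v for k, v in c["p_values"].items()},
                    }
                )
        if rows:
            df = pd.DataFrame(rows)
            _df_to_csv(df, out_dir / "context_dependence.csv")
            result.tables["context"] = df

    if "pca" in stages:
        load_rows, var_rows = [], []
        for fly, ses in zip(experiment.flies, sessions):
            pca = WalkingPCA()
            labels_neural = [
                nearest_labels(tr.labels, tr.label_times, tr.traces.frame_times)
                for tr in fly.trials
            ]
            try:
                pca.fit(
                    [tr.traces.values for tr in fly.trials],
                    labels_neural,
                    dt=1.0 / experiment.config.neural_rate,
                )
            except ValueError as e:
                log.info("pca skipped (fly %s): %s", fly.fly_id, e)
                continue
            lf = pca.loadings_frame()
            lf.insert(0, "fly_id", fly.fly_id)
            load_rows.append(lf)
            var_rows.append(
                pd.DataFrame(
                    {
                        "fly_id": fly.fly_id,
                        "component": np.arange(pca.explained_variance_ratio_.size) + 1,
                        "explained_variance_ratio": pca.explained_variance_ratio_,
                    }
                )
            )
        if load_rows:
            _df_to_csv(pd.concat(load_rows, ignore_index=True), out_dir / "pca_loadings.csv")
            var = pd.concat(var_rows, ignore_index=True)
            _df_to_csv(var, out_dir / "pca_variance.csv")
            result.tables["pca_variance"] = var
            first2 = var[var.component <= 2].groupby("fly_id").explained_variance_ratio.sum()
            summary["pc12_variance_mean"] = float(first2.mean())

    if "decoding" in stages:
        all_scores, comps = [], {}
        for ses in sessions:
            resid = behavior_residuals(ses, cv)
            for odor in ("ACV", "MSC"):
                sc = residual_odor_classifier(ses, odor, cv, residuals=resid)
                sc.insert(0, "fly_id", ses.fly_id)
                all_scores.append(sc)
        scores = pd.concat(all_scores, ignore_index=True)
        _df_to_csv(scores, out_dir / "odor_decoding_scores.csv")
        result.tables["decoding"] = scores
        for odor in ("ACV", "MSC"):
            comps[odor] = compare_feature_sets(scores[scores.odor == odor])
        with open(out_dir / "odor_decoding_tests.json", "w") as f:
            json.dump(comps, f, indent=2)
        summary["odor_decoding"] = comps

    if "spatial" in stages:
        rows = []
        if assign_all is None:
            log.info("spatial: encoding stage not run; stage skipped")
        else:
            pos = []
            for fly in experiment.flies:
                p = pd.DataFrame(fly.trials[0].roi_positions, columns=["x", "z"])
                p.insert(0, "neuron_id", np.arange(len(p)))
                p.insert(0, "fly_id", fly.fly_id)
                pos.append(p)
            pos = pd.concat(pos, ignore_index=True)
            merged = pos.merge(assign_all, on=["fly_id", "neuron_id"])
            ref = merged[["x"]].to_numpy().ravel()
            bw = select_bandwidth_loo(ref)
            grid = np.linspace(ref.min() - 5, ref.max() + 5, 101)
            for beh in BEHAVIOR_STATES:
                subset = merged.loc[merged.assigned == beh, "x"].to_numpy()
                if subset.size < 2:
                    continue
                dm = normalized_density(subset, ref, grid, bandwidth=bw)
                rows.append(
                    pd.DataFrame(
                        {
                            "behavior": beh,
                            "x": grid,
                            "density": dm.density,
                            "reference": dm.reference_density,
                            "ratio": dm.ratio,
                        }
                    )
                )
        if rows:
            df = pd.concat(rows, ignore_index=True)
            _df_to_csv(df, out_dir / "spatial_density.csv")
            result.tables["spatial"] = df

    if "events" in stages:
        ev_rows = []
        for fly, ses in zip(experiment.flies, sessions):
            for tr in fly.trials:
                for beh in BEHAVIOR_STATES:
                    for ev in EV.extract_isolated_events(tr.labels, tr.label_times, beh, tr.trial_id):
                        ev_rows.append(
                            {
                                "fly_id": fly.fly_id,
                                "trial_id": ev.trial_id,
                                "behavior": ev.behavior,
                                "onset": ev.onset,
                                "end": ev.end,
                            }
                        )
            corr = EV.correlation_analysis([tr.traces.values for tr in fly.trials])
            ward = EV.ward_ordering(corr["neuron_corr"])
            np.savetxt(
                out_dir / f"correlation_fly{fly.fly_id}.csv", corr["neuron_corr"], delimiter=",", fmt="%.6g"
            )
            np.savetxt(
                out_dir / f"ward_order_fly{fly.fly_id}.csv",
                ward["leaf_order"][None, :],
                delimiter=",",
                fmt="%d",
            )
        df = pd.DataFrame(ev_rows)
        _df_to_csv(df, out_dir / "events.csv")
        result.tables["events"] = df
        summary["n_events"] = int(len(df))

    result.summary = summary
    with open(out_dir / "summary.json", "w") as f:
        json.dump(summary, f, indent=2, default=float)
    return result


def recovery_report(experiment: Experiment, result: PipelineResult) -> dict:
    """Score pipeline outputs against the synthetic ground truth."""
    gt = experiment.ground_truth_frame()
    report: dict = {"seed": result.summary.get("seed")}

    if "assignment" in result.tables:
        m = result.tables["assignment"].merge(gt, on=["fly_id", "neuron_id"])
        cls2beh = {"walk": "walking", "head_groom": "head_grooming", "rest": "resting"}
        wg = m[m.encoding_class.isin(["walk", "head_groom"])]
        correct = wg.apply(lambda r: r.assigned == cls2beh[r.encoding_class], axis=1)
        report["walk_groom_assignment_accuracy"] = float(correct.mean())
        none_sub = m[m.encoding_class == "none"]
        report["none_unassigned_rate"] = float((none_sub.assigned == "none").mean())

    if "rotation_per_neuron" in result.tables:
        per = result.tables["rotation_per_neuron"].pivot_table(
            index=["fly_id", "neuron_id"], columns="target", values="uev"
        ).reset_index()
        m = per.merge(gt, on=["fly_id", "neuron_id"])
        tl = m[m.encoding_class == "turn_left"]
        tr = m[m.encoding_class == "turn_right"]
        n_ok = int((tl.turn_left > tl.turn_right).sum() + (tr.turn_right > tr.turn_left).sum())
        report["turn_side_accuracy"] = n_ok / max(len(tl) + len(tr), 1)

    if "rotation_population" in result.tables:
        pop = result.tables["rotation_population"]
        wo = pop[pop.walking_only]
        report["turning_uev_gt_speed_uev"] = bool(
            wo[wo.target == "turning"].uev_neural.mean()
            > wo[wo.target == "speed"].uev_neural.mean()
        )

    if "odor_uev" in result.tables:
        m = result.tables["odor_uev"].merge(gt, on=["fly_id", "neuron_id"])
        is_odor_gt = m.encoding_class.isin(["odor_acv", "odor_msc"])
        pred = (m.uev_acv > 0.05) | (m.uev_msc > 0.05)
        tp = int((pred & is_odor_gt).sum())
        report["odor_detection_precision"] = tp / max(int(pred.sum()), 1)
        report["odor_detection_recall"] = tp / max(int(is_odor_gt.sum()), 1)

    if "rotation_per_neuron" in result.tables:
        # spatial recovery: do the planted left/right turn populations peak on
        # the correct side of the medial-lateral axis?
        per = result.tables["rotation_per_neuron"]
        pos = []
        for fly in experiment.flies:
            p = pd.DataFrame(fly.trials[0].roi_positions, columns=["x", "z"])
            p.insert(0, "neuron_id", np.arange(len(p)))
            p.insert(0, "fly_id", fly.fly_id)
            pos.append(p)
        pos = pd.concat(pos, ignore_index=True)
        ref = pos["x"].to_numpy()
        grid = np.linspace(ref.min() - 5, ref.max() + 5, 101)
        try:
            bw = select_bandwidth_loo(ref)
            sides = {}
            for tgt, planted_sign in (("turn_left", -1.0), ("turn_right", 1.0)):
                sub = per[(per.target == tgt) & (per.uev > 0.05)]
                merged = sub.merge(pos, on=["fly_id", "neuron_id"])
                if len(merged) < 2:
                    continue
                dm = normalized_density(merged["x"].to_numpy(), ref, grid, bandwidth=bw)
                peak_x = float(grid[int(np.nanargmax(dm.ratio))])
                sides[tgt] = bool(np.sign(peak_x) == planted_sign)
            if sides:
                report["kde_turn_peak_side_correct"] = all(sides.values())
                report["kde_turn_peak_sides"] = sides
        except ValueError as e:
            report["kde_turn_peak_side_correct"] = f"skipped: {e}"

    if "label" in result.tables:
        report["label_frame_accuracy"] = float(
            result.tables["label"].frame_accuracy.mean()
        )

    if "pca_variance" in result.tables:
        var = result.tables["pca_variance"]
        report["pc12_variance_mean"] = float(
            var[var.component <= 2].groupby("fly_id").explained_variance_ratio.sum().mean()
        )

    if "odor_decoding" in result.summary:
        report["odor_decoding"] = result.summary["odor_decoding"]

    return report
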