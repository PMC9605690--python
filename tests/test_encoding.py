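import numpy as np
import pandas as pd
import pytest

from conftest import neuron_index
from dnpop.design import concat_designs, convolved_design
from dnpop.encoding import (
    assemble_session,
    assign_behaviors,
    context_dependent_encoding,
    disambiguate_sequential_behaviors,
    joint_angle_uev,
    neuron_behavior_encoding_map,
    odor_uev,
    odor_uev_population,
    rotation_encoding,
)
from dnpop.regression import CVConfig
from dnpop.signals import convolve_with_crf, resample_to_neural
from dnpop.simulate import GeneratorConfig, generate_experiment

CV = CVConfig()


@pytest.fixture(scope="module")
def encoding_map(small_session):
    return neuron_behavior_encoding_map(small_session, CV)


class TestEncodingMap:
    def test_planted_walk_and_groom_neurons_assigned(self, encoding_map, small_session, small_ground_truth):
        assign = assign_behaviors(encoding_map)
        merged = assign.merge(small_ground_truth, on=["fly_id", "neuron_id"])
        walk = merged[merged.encoding_class == "walk"]
        groom = merged[merged.encoding_class == "head_groom"]
        assert (walk.assigned == "walking").mean() >= 0.9
        assert (groom.assigned == "head_grooming").mean() >= 0.9

    def test_noise_neurons_fall_below_cutoff(self, encoding_map, small_ground_truth):
        assign = assign_behaviors(encoding_map)
        merged = assign.merge(small_ground_truth, on=["fly_id", "neuron_id"])
        none = merged[merged.encoding_class == "none"]
        assert (none.assigned == "none").all()
        assert (none.max_r2 < 0.05).all()

    def test_r2_bounded(self, encoding_map):
        assert (encoding_map.r2 >= 0).all() and (encoding_map.r2 <= 1).all()

    def test_noiseless_neurons_separate_behaviors(self, small_cfg):
        cfg = GeneratorConfig(
            seed=21,
            n_flies=1,
            n_trials=2,
            trial_duration=240.0,
            noise_sigma=0.0,
            class_proportions={"walk": 0.5, "head_groom": 0.5},
            n_odor_neurons=0,
            n_neurons_range=(2, 2),
        )
        exp = generate_experiment(cfg)
        ses = assemble_session(exp.flies[0].trials, cfg.kernel())
        gt = exp.flies[0].ground_truth_frame()
        emap = neuron_behavior_encoding_map(ses, CV)
        piv = emap.pivot_table(index="neuron_id", columns="behavior", values="r2")
        for row in gt.itertuples():
            own = "walking" if row.encoding_class == "walk" else "head_grooming"
            other = "head_grooming" if own == "walking" else "walking"
            assert piv.loc[row.neuron_id, own] > 0.9
            assert piv.loc[row.neuron_id, own] > piv.loc[row.neuron_id, other]


class TestDisambiguation:
    def test_groom_neuron_not_attributed_to_rubbing(self, small_session, small_ground_truth):
        # front leg rubbing reliably follows head grooming in the generator,
        # so the naive map can confuse them; UEV on the restricted model must not
        i = neuron_index(small_session, small_ground_truth, "head_groom")
        r = disambiguate_sequential_behaviors(
            small_session, i, "head_grooming", "front_leg_rubbing", CV
        )
        assert r["uev_a"] > 5 * max(r["uev_b"], 1e-3)

    def test_identical_regressors_both_near_zero(self, small_session, small_ground_truth):
        # passing the same behavior twice makes the two regressors perfectly
        # collinear: shuffling either copy is compensated by its twin
        ses = small_session
        i = neuron_index(ses, small_ground_truth, "walk")
        r = disambiguate_sequential_behaviors(ses, i, "walking", "walking", CV)
        assert r["uev_a"] < 0.05 and r["uev_b"] < 0.05

    def test_equal_frame_counts(self, small_session, small_ground_truth):
        i = neuron_index(small_session, small_ground_truth, "head_groom")
        r = disambiguate_sequential_behaviors(
            small_session, i, "head_grooming", "front_leg_rubbing", CV
        )
        lab = small_session.labels
        n_a = (lab == "head_grooming").sum()
        n_b = (lab == "front_leg_rubbing").sum()
        assert r["n_frames_per_behavior"] == min(n_a, n_b)


class TestRotationEncoding:
    @pytest.fixture(scope="class")
    def turn_experiment(self):
        # turn- and speed-dominated population with low noise: 10 turn
        # neurons against 2 weaker speed neurons
        cfg = GeneratorConfig(
            seed=41,
            n_flies=1,
            n_trials=3,
            trial_duration=360.0,
            noise_sigma=0.5,
            class_proportions={"turn_left": 0.35, "turn_right": 0.35, "speed": 0.15},
            amplitudes={**GeneratorConfig().amplitudes, "speed": 0.3},
            n_odor_neurons=0,
            n_neurons_range=(14, 14),
        )
        exp = generate_experiment(cfg)
        return exp, assemble_session(exp.flies[0].trials, cfg.kernel())

    def test_turn_neurons_lateralized(self, turn_experiment):
        exp, ses = turn_experiment
        gt = exp.flies[0].ground_truth_frame()
        per = rotation_encoding(ses, CV, per_neuron=True)
        piv = per.pivot_table(index="neuron_id", columns="target", values="uev")
        merged = piv.merge(gt, on="neuron_id")
        tl = merged[merged.encoding_class == "turn_left"]
        tr = merged[merged.encoding_class == "turn_right"]
        assert len(tl) and len(tr)
        assert (tl.turn_left > 0.05).all()
        assert (tl.turn_left > tl.turn_right).all()
        assert (tr.turn_right > tr.turn_left).all()

    def test_population_turning_exceeds_speed_when_walking_only(self, turn_experiment):
        _, ses = turn_experiment
        pop = rotation_encoding(ses, CV, walking_only=True)
        turning = pop.loc[pop.target == "turning", "uev_neural"].iloc[0]
        speed = pop.loc[pop.target == "speed", "uev_neural"].iloc[0]
        assert turning > speed

    def test_population_r2_not_below_neural_uev(self, turn_experiment):
        _, ses = turn_experiment
        pop = rotation_encoding(ses, CV, walking_only=False)
        assert (pop.r2 + 1e-9 >= pop.uev_neural).all()


def _angle_design(session, fly, kernel, extra=None):
    designs = []
    for tr in fly.trials:
        regs = {
            "front_angle": tr.pose.joint_positions[0, 0],
            "hind_angle": tr.pose.joint_positions[2, 0],
        }
        if extra:
            regs.update({k: f(tr) for k, f in extra.items()})
        designs.append(
            convolved_design(
                regs, tr.label_times, tr.traces.frame_times, kernel,
                trial_id=tr.trial_id, groups={"angles": list(regs)},
            )
        )
    return concat_designs(designs)


class TestJointAngleUEV:
    def test_behavior_driven_neuron_has_no_angle_uev(self, small_session, small_fly, small_cfg, small_ground_truth):
        i = neuron_index(small_session, small_ground_truth, "walk")
        ad = _angle_design(small_session, small_fly, small_cfg.kernel())
        out = joint_angle_uev(
            small_session, i, ad,
            {"all": ["front_angle", "hind_angle"], "front": ["front_angle"], "hind": ["hind_angle"]},
            CV,
        )
        assert out["all"] < 0.05
        assert out["front"] < 0.05 and out["hind"] < 0.05

    def test_angle_driven_neuron_recovered(self, small_fly, small_cfg, small_session):
        # a slowly varying "joint angle" uncorrelated with the behavior
        # labels; the leg oscillations themselves are too fast for the crf
        from scipy.ndimage import gaussian_filter1d

        kernel = small_cfg.kernel()
        rng = np.random.default_rng(0)
        slow = {
            tr.trial_id: gaussian_filter1d(rng.standard_normal(tr.label_times.size), 100.0) * 12.0
            for tr in small_fly.trials
        }
        traces = []
        for tr in small_fly.trials:
            conv = convolve_with_crf(3.0 * slow[tr.trial_id], kernel)
            res = resample_to_neural(conv, tr.label_times, tr.traces.frame_times)
            traces.append(res + 0.3 * rng.standard_normal(res.size))
        import copy

        ses2 = copy.copy(small_session)
        ses2.traces = np.vstack([small_session.traces, np.concatenate(traces)[None, :]])
        ses2.neuron_ids = np.arange(ses2.traces.shape[0])
        ad = _angle_design(
            ses2, small_fly, kernel, extra={"slow_angle": lambda tr: slow[tr.trial_id]}
        )
        out = joint_angle_uev(
            ses2, ses2.traces.shape[0] - 1, ad,
            {"slow": ["slow_angle"], "front": ["front_angle"], "hind": ["hind_angle"]},
            CV,
        )
        assert out["slow"] > 0.3
        assert out["front"] < 0.05 and out["hind"] < 0.05

    def test_unknown_group_member_raises(self, small_session, small_fly, small_cfg):
        ad = _angle_design(small_session, small_fly, small_cfg.kernel())
        with pytest.raises(KeyError):
            joint_angle_uev(small_session, 0, ad, {"bad": ["missing"]}, CV)


class TestOdorUEV:
    @pytest.fixture(scope="class")
    def table(self, small_session):
        return odor_uev_population(small_session, CV)

    def test_planted_odor_neurons_specific(self, table, small_ground_truth):
        merged = table.merge(small_ground_truth, on=["fly_id", "neuron_id"])
        acv = merged[merged.encoding_class == "odor_acv"]
        msc = merged[merged.encoding_class == "odor_msc"]
        assert (acv.uev_acv > 5 * np.maximum(acv.uev_msc, 1e-3)).all()
        assert (msc.uev_msc > 5 * np.maximum(msc.uev_acv, 1e-3)).all()

    def test_behavior_neuron_has_no_odor_uev(self, table, small_ground_truth):
        merged = table.merge(small_ground_truth, on=["fly_id", "neuron_id"])
        walk = merged[merged.encoding_class == "walk"]
        assert (walk.uev_acv < 0.05).all() and (walk.uev_msc < 0.05).all()
        assert np.allclose(walk.r2_behavior, walk.r2_full, atol=0.05)

    def test_noise_neuron_all_near_zero(self, table, small_ground_truth):
        merged = table.merge(small_ground_truth, on=["fly_id", "neuron_id"])
        none = merged[merged.encoding_class == "none"]
        assert (none.r2_full < 0.02).all()
        assert (none.uev_acv < 0.02).all() and (none.uev_msc < 0.02).all()

    def test_scalar_matches_population(self, small_session, table):
        r = odor_uev(small_session, 0, CV)
        row = table[table.neuron_id == small_session.neuron_ids[0]].iloc[0]
        assert r["r2_full"] == pytest.approx(row.r2_full, abs=1e-9)


class TestContextDependence:
    @pytest.fixture(scope="class")
    def flat_context_session(self):
        # no odor modulation of behavior: contexts are statistically
        # identical; default trial count/duration so each context has the
        # same number of presentation blocks
        cfg = GeneratorConfig(
            seed=31,
            n_flies=1,
            n_trials=5,
            trial_duration=540.0,
            acv_walk_multiplier=1.0,
            acv_speed_multiplier=1.0,
            acv_turn_multiplier=1.0,
            msc_walk_multiplier=1.0,
        )
        exp = generate_experiment(cfg)
        return exp, assemble_session(exp.flies[0].trials, cfg.kernel())

    def test_context_independent_neuron(self, flat_context_session):
        exp, ses = flat_context_session
        gt = exp.flies[0].ground_truth_frame()
        i = neuron_index(ses, gt, "walk")
        out = context_dependent_encoding(ses, i, "walking", CV)
        assert out["p_values"]["ACV_vs_MSC"] > 0.05
        assert out["p_values"]["ACV_vs_air"] > 0.05

    def test_context_dependent_neuron_detected(self, flat_context_session):
        exp, ses = flat_context_session
        kernel = exp.config.kernel()
        rng = np.random.default_rng(1)
        rows = []
        for tr in exp.flies[0].trials:
            walk = (tr.labels == "walking").astype(float)
            acv = np.zeros(tr.label_times.size)
            for s, e, name in tr.odor_intervals:
                if name == "ACV":
                    acv[(tr.label_times >= s) & (tr.label_times < e)] = 1.0
            conv = convolve_with_crf(6.0 * walk * acv, kernel)
            res = resample_to_neural(conv, tr.label_times, tr.traces.frame_times)
            rows.append(res + rng.standard_normal(res.size))
        import copy

        ses2 = copy.copy(ses)
        ses2.traces = np.vstack([ses.traces, np.concatenate(rows)[None, :]])
        ses2.neuron_ids = np.arange(ses2.traces.shape[0])
        out = context_dependent_encoding(ses2, ses2.traces.shape[0] - 1, "walking", CV)
        assert out["r2_per_context"]["ACV"] > out["r2_per_context"]["air"] + 0.2
        assert out["p_values"]["ACV_vs_air"] < 0.05

    def test_air_subsample_matches_odor_amount(self, small_session, small_ground_truth):
        i = neuron_index(small_session, small_ground_truth, "walk")
        out = context_dependent_encoding(small_session, i, "walking", CV)
        n_air = out["n_frames_air_subsampled"]
        n_acv = int(small_session.odor_mask("ACV").sum())
        n_msc = int(small_session.odor_mask("MSC").sum())
        assert 0.5 * min(n_acv, n_msc) <= n_air <= 1.5 * max(n_acv, n_msc)
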