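"""Synthetic trajectory and outcome generators."""

import numpy as np
import pandas as pd
import pytest

from courtmetrics.occupancy import entropy_table, trial_entropy
from courtmetrics.synthetic import (
    DEFAULT_ENTROPY_COEFS,
    ExperimentDesign,
    GOAL_XY,
    PLAY_WAYPOINTS,
    RegimeSpec,
    cell_means_from_coefs,
    default_design,
    generate_entropy_table,
    generate_experiment,
    generate_trial,
)


def _noise_free(spec: RegimeSpec) -> RegimeSpec:
    spec.noise_mae = (0.0, 0.0)
    spec.waypoint_jitter_cm = 0.0
    spec.speed_jitter = 0.0
    spec.wander_sd = 0.0
    return spec


class TestGenerateTrial:
    def test_stationary_without_noise_is_constant(self):
        spec = _noise_free(RegimeSpec("stationary", waypoints=[(400.0, 600.0)]))
        df = generate_trial({"O1": spec}, seed=1)
        assert (df["x_cm"] == 400.0).all() and (df["y_cm"] == 600.0).all()
        assert trial_entropy(df["x_cm"].to_numpy(), df["y_cm"].to_numpy()) == 0.0

    def test_scripted_kinematics_arrive_and_hold(self):
        spec = _noise_free(
            RegimeSpec("scripted_play", waypoints=[(100.0, 100.0), (1100.0, 100.0)],
                       speed=200.0)
        )
        df = generate_trial({"O1": spec}, seed=1)
        x = df.sort_values("frame")["x_cm"].to_numpy()
        # 1000 cm at 200 cm/s -> arrival at t = 5 s = frame 100, then hold
        assert x[0] == pytest.approx(100.0)
        assert x[99] < 1100.0
        assert np.allclose(x[100:], 1100.0)

    def test_waypoint_outside_court_rejected(self):
        spec = RegimeSpec("scripted_play", waypoints=[(100.0, 100.0), (1600.0, 100.0)])
        with pytest.raises(ValueError, match="court"):
            generate_trial({"O1": spec}, seed=1)

    def test_shadow_tracks_attacker_at_offset(self):
        o = _noise_free(RegimeSpec("scripted_play",
                                   waypoints=PLAY_WAYPOINTS["drive_middle"]))
        d = _noise_free(RegimeSpec("shadow", target_role="O1", offset_cm=80.0))
        df = generate_trial({"O1": o, "D1": d}, seed=1)
        a = df[df.role == "O1"].sort_values("frame")[["x_cm", "y_cm"]].to_numpy()
        b = df[df.role == "D1"].sort_values("frame")[["x_cm", "y_cm"]].to_numpy()
        gaps = np.linalg.norm(a - b, axis=1)
        assert np.allclose(gaps, 80.0, atol=1e-6)
        # defender sits between attacker and goal
        d_goal = np.linalg.norm(np.asarray(GOAL_XY) - b, axis=1)
        a_goal = np.linalg.norm(np.asarray(GOAL_XY) - a, axis=1)
        assert (d_goal < a_goal).all()

    def test_mixture_beats_single_play_and_loses_to_walk(self):
        """Movement-diversity ordering at the scale of 21 trials per regime."""
        def mean_entropy(spec_factory):
            hs = []
            for trial in range(1, 22):
                spec = spec_factory()
                df = generate_trial({"O3": spec}, seed=77, trial=trial)
                hs.append(trial_entropy(df["x_cm"].to_numpy(), df["y_cm"].to_numpy()))
            return np.mean(hs)

        h_stat = mean_entropy(lambda: RegimeSpec("stationary", waypoints=[(350.0, 500.0)]))
        h_single = mean_entropy(
            lambda: RegimeSpec("scripted_play", waypoints=PLAY_WAYPOINTS["deep_corner"],
                               wander_sd=60.0)
        )
        h_mix = mean_entropy(
            lambda: RegimeSpec("play_mixture",
                               plays=["hand_off", "pick_and_roll", "deep_corner", "goal_cut"],
                               wander_sd=60.0)
        )
        h_rw = mean_entropy(lambda: RegimeSpec("random_walk", waypoints=[(350.0, 500.0)]))
        assert h_stat < h_single < h_mix < h_rw


class TestGenerateExperiment:
    def test_default_design_cardinality(self, default_experiment):
        trajs = default_experiment.groupby(["condition", "session", "trial", "role"])
        assert len(trajs) == 504  # 4 conditions x 21 trials x 6 roles

    def test_same_seed_identical(self):
        d1 = default_design(seed=5)
        d2 = default_design(seed=5)
        small = {c: d1.conditions[c] for c in ("high_expertise", "random_walk")}
        e1 = generate_experiment(ExperimentDesign(small, n_sessions=1,
                                                  trials_per_session=2, seed=5))
        small2 = {c: d2.conditions[c] for c in ("high_expertise", "random_walk")}
        e2 = generate_experiment(ExperimentDesign(small2, n_sessions=1,
                                                  trials_per_session=2, seed=5))
        pd.testing.assert_frame_equal(e1, e2)

    def test_conditions_have_distinct_trajectories(self, default_experiment):
        """Each condition gets its own randomness, even for identical regimes."""
        d = default_experiment
        a = d[(d.condition == "high_expertise") & (d.role == "O1")]["x_cm"].to_numpy()
        b = d[(d.condition == "low_after_tips") & (d.role == "O1")]["x_cm"].to_numpy()
        assert not np.allclose(a[: len(b)], b[: len(a)])

    def test_entropy_ordering_across_conditions(self, default_experiment):
        ent = entropy_table(default_experiment)
        means = ent.groupby("condition")["H_bits"].mean()
        assert means["random_walk"] > means[["high_expertise", "low_before_tips",
                                             "low_after_tips"]].max()
        o3 = ent[ent.role == "O3"].groupby("condition")["H_bits"].mean()
        assert o3["high_expertise"] > o3["low_after_tips"]


class TestGenerateEntropyTable:
    def test_zero_variance_equals_cell_means(self):
        tab = generate_entropy_table(var_session=0, var_trial=0, var_resid=0, seed=4)
        mus = cell_means_from_coefs()
        for (cond, role), mu in mus.items():
            got = tab[(tab.condition == cond) & (tab.role == role)]["H_bits"]
            assert np.allclose(got, mu)

    def test_cardinality_and_determinism(self):
        a = generate_entropy_table(seed=9)
        b = generate_entropy_table(seed=9)
        assert len(a) == 252  # 4 conditions x 3 roles x 21 trials
        pd.testing.assert_frame_equal(a, b)

    def test_default_cell_means_reflect_coefs(self):
        mus = cell_means_from_coefs()
        c = DEFAULT_ENTROPY_COEFS
        assert mus[("low_before_tips", "O1")] == c["intercept"]
        assert mus[("random_walk", "O3")] == pytest.approx(
            c["intercept"] + c["cond"]["random_walk"] + c["role"]["O3"]
            + c["interaction"][("random_walk", "O3")]
        )

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            generate_entropy_table(var_resid=-1.0)

    def test_variance_components_recovered(self):
        """Empirical moments across replicates match the generating variances."""
        sess_means, resid_vars = [], []
        for seed in range(200):
            tab = generate_entropy_table(seed=seed)
            mus = cell_means_from_coefs()
            centered = tab.assign(
                dev=tab.apply(lambda r: r.H_bits - mus[(r.condition, r.role)], axis=1)
            )
            # per-(session, trial) means estimate u_s + v_st; their residuals e
            cell = centered.groupby(["session", "trial"])["dev"].transform("mean")
            resid_vars.append((centered["dev"] - cell).var(ddof=1))
        # E[var of within-cell residuals] = var_resid * (1 - 1/n_per_cell)
        n_cell = 12  # 4 conditions x 3 roles share each (session, trial)
        expect = 0.565 * (1 - 1 / n_cell)
        assert np.mean(resid_vars) == pytest.approx(expect, rel=0.05)
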