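"""Design-structure and distributional checks for the trial generators."""

import numpy as np
import pandas as pd
import pytest

from pongocog import (
    ChoiceGenParams,
    DotProbeGenParams,
    StimulusPair,
    schedule_dotprobe,
    schedule_preference,
    simulate_choices,
    simulate_dotprobe,
)
from pongocog.synthetic import default_flange_pairs, default_symmetry_pairs


class TestStimulusPair:
    def test_width_diff_only_for_flange_task(self):
        with pytest.raises(ValueError):
            StimulusPair("X1", "symmetry", width_diff=10.0)
        with pytest.raises(ValueError):
            StimulusPair("X1", "flange")
        with pytest.raises(ValueError):
            StimulusPair("X1", "flange", width_diff=-1.0)


class TestScheduleDotprobe:
    @pytest.mark.parametrize(
        "n_pairs, n_sessions, per_session",
        [(72, 6, 24), (80, 8, 20), (1, 1, 2)],
    )
    def test_every_pair_probed_once_per_congruence(self, n_pairs, n_sessions, per_session):
        pairs = (
            default_flange_pairs(n_pairs, seed=0)
            if n_pairs != 80
            else default_symmetry_pairs(n_pairs)
        )
        plan = schedule_dotprobe(pairs, n_sessions, per_session, seed=5)
        assert len(plan) == 2 * n_pairs
        per_pair = plan.groupby("pair_id")["congruence"].agg(["count", "nunique"])
        assert (per_pair["count"] == 2).all()
        assert (per_pair["nunique"] == 2).all()
        assert (plan.groupby("session_id").size() == per_session).all()

    def test_probe_sides_balanced_within_session(self):
        plan = schedule_dotprobe(default_flange_pairs(72, seed=0), 6, 24, seed=5)
        counts = plan.groupby("session_id")["probe_side"].value_counts().unstack()
        assert (abs(counts["left"] - counts["right"]) <= 1).all()

    def test_size_mismatch_rejected_with_message(self):
        with pytest.raises(ValueError, match="144"):
            schedule_dotprobe(default_flange_pairs(72, seed=0), 6, 23, seed=5)

    def test_duplicate_pair_ids_rejected(self):
        pairs = [StimulusPair("F1", "flange", 10.0)] * 2
        with pytest.raises(ValueError, match="unique"):
            schedule_dotprobe(pairs, 1, 4, seed=0)

    def test_seed_determinism(self):
        pairs = default_flange_pairs(72, seed=0)
        a = schedule_dotprobe(pairs, 6, 24, seed=7)
        b = schedule_dotprobe(pairs, 6, 24, seed=7)
        pd.testing.assert_frame_equal(a, b)


@pytest.fixture(scope="module")
def big_plan():
    # large single-subject grid for moment checks
    return schedule_dotprobe(default_flange_pairs(5000, seed=1), 10, 1000, seed=2)


class TestSimulateDotprobe:
    def test_null_effect_gives_no_condition_gap(self, big_plan):
        params = DotProbeGenParams(
            b_congruent_ms=0.0, session_sd_ms=0.0, p_anticipatory=0.0, p_slow=0.0
        )
        trials = simulate_dotprobe(big_plan, params, seed=3)
        gap = (
            trials.loc[trials.congruence == "congruent", "rt_ms"].mean()
            - trials.loc[trials.congruence == "incongruent", "rt_ms"].mean()
        )
        se = 2 * trials["rt_ms"].std() / np.sqrt(len(trials) / 2)
        assert abs(gap) < 3 * se

    def test_sum_coding_doubles_the_condition_gap(self, big_plan):
        params = DotProbeGenParams(
            b_congruent_ms=-10.0,
            session_sd_ms=0.0,
            resid_scale_ms=20.0,
            resid_df=30.0,
            p_anticipatory=0.0,
            p_slow=0.0,
        )
        trials = simulate_dotprobe(big_plan, params, seed=3)
        gap = (
            trials.loc[trials.congruence == "congruent", "rt_ms"].mean()
            - trials.loc[trials.congruence == "incongruent", "rt_ms"].mean()
        )
        assert gap == pytest.approx(-20.0, abs=1.0)

    def test_anticipatory_contamination_rate(self, big_plan):
        params = DotProbeGenParams(p_anticipatory=0.1, p_slow=0.0)
        trials = simulate_dotprobe(big_plan, params, seed=4)
        n = len(trials)
        n_antic = (trials["contaminant"] == "anticipatory").sum()
        assert (trials.loc[trials["contaminant"] == "anticipatory", "rt_ms"] < 200).all()
        assert abs(n_antic - 0.1 * n) < 4 * np.sqrt(n * 0.1 * 0.9)

    def test_median_close_to_intercept_without_contamination(self, big_plan):
        params = DotProbeGenParams(
            b_congruent_ms=0.0, b_left_ms=0.0, session_sd_ms=0.0,
            p_anticipatory=0.0, p_slow=0.0,
        )
        trials = simulate_dotprobe(big_plan, params, seed=5)
        n = len(trials)
        # SE of the median of a t(5) location-scale sample
        se = 1.2533 * params.resid_scale_ms / np.sqrt(n)
        assert abs(np.median(trials["rt_ms"]) - params.intercept_ms) < 3 * se * 1.5

    def test_clipping_flagged(self):
        plan = schedule_dotprobe(default_flange_pairs(50, seed=1), 2, 50, seed=2)
        params = DotProbeGenParams(
            intercept_ms=60.0, resid_scale_ms=200.0, p_anticipatory=0.0, p_slow=0.0
        )
        trials = simulate_dotprobe(plan, params, seed=3)
        assert (trials["rt_ms"] >= 50.0).all()
        assert trials["clipped"].any()

    def test_seed_determinism(self, big_plan):
        params = DotProbeGenParams()
        a = simulate_dotprobe(big_plan, params, seed=9)
        b = simulate_dotprobe(big_plan, params, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestSchedulePreference:
    def test_design_arithmetic(self):
        plan = schedule_preference([f"S{i}" for i in range(6)], seed=1)
        assert len(plan) == 6 * 6 * 24
        assert (plan["phase"] == "choice").sum() == 576

    def test_order_groups_split_evenly(self):
        plan = schedule_preference([f"S{i}" for i in range(6)], seed=1)
        orders = plan.groupby("subject_id")["order"].first()
        assert (orders == "red_first").sum() == 3

    def test_blocks_contiguous_and_forced_precede_choice(self):
        plan = schedule_preference(["A", "B"], seed=2)
        for _, subj in plan.groupby("subject_id"):
            block_seq = subj.groupby("session_id", sort=False)["block"].first()
            # exactly one change-point between the two colour blocks
            assert (block_seq != block_seq.shift()).sum() == 2
            for _, sess in subj.groupby("session_id"):
                sess = sess.sort_values("trial_index")
                assert (sess["phase"].iloc[:8] == "forced").all()
                assert (sess["phase"].iloc[8:] == "choice").all()
                forced = sess.iloc[:8]
                assert (forced["forced_colour"] == "red").sum() == 4

    def test_heights_in_range_and_centred(self):
        plan = schedule_preference([f"S{i}" for i in range(20)], seed=3)
        h = plan["flanged_dot_height"]
        assert (h.abs() <= 0.35 + 1e-12).all()
        # R*cos(uniform angle) has mean 0 and sd R/sqrt(2)
        assert abs(h.mean()) < 4 * (0.35 / np.sqrt(2)) / np.sqrt(len(h))

    def test_empty_subjects_rejected(self):
        with pytest.raises(ValueError):
            schedule_preference([], seed=0)


class TestSimulateChoices:
    def test_null_model_marginal_near_half(self):
        plan = schedule_preference([f"S{i}" for i in range(110)], seed=4)
        params = ChoiceGenParams(
            b_green=0.0, b_order=0.0, b_height=0.0,
            subject_sd=0.0, session_sd=0.0, colour_slope_sd=0.0,
        )
        trials = simulate_choices(plan, params, seed=5)
        choice = trials.loc[trials["phase"] == "choice", "choice"]
        assert len(choice) > 10_000
        assert 0.48 <= choice.mean() <= 0.52

    def test_height_effect_direction(self):
        plan = schedule_preference([f"S{i}" for i in range(30)], seed=6)
        params = ChoiceGenParams(
            b_green=0.0, b_order=0.0, b_height=4.05,
            subject_sd=0.0, session_sd=0.0, colour_slope_sd=0.0,
        )
        trials = simulate_choices(plan, params, seed=7)
        choice = trials.loc[trials["phase"] == "choice"]
        low = choice.loc[choice["flanged_dot_height"] > 0.25, "choice"].mean()
        high = choice.loc[choice["flanged_dot_height"] < -0.25, "choice"].mean()
        assert low > 0.75 > 0.25 > high

    def test_forced_trials_deterministic(self, preference_trials):
        forced = preference_trials.loc[preference_trials["phase"] == "forced"]
        expected = (forced["forced_colour"] == forced["flanged_colour"]).astype(int)
        assert (forced["choice"] == expected).all()

    def test_seed_determinism(self):
        plan = schedule_preference(["A", "B", "C"], seed=8)
        a = simulate_choices(plan, ChoiceGenParams(), seed=9)
        b = simulate_choices(plan, ChoiceGenParams(), seed=9)
        pd.testing.assert_frame_equal(a, b)
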