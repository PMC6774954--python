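import numpy as np
import pandas as pd
import pytest

from iplgaze import (CHANCE_TRANSFORMED, aggregate_scores, arcsinsqrt,
                     baseline_corrected, binned_target_proportion,
                     pair_difference_score, pair_scores, participant_series)

from conftest import make_trial, segments_to_gaze


def _pair_fixture(durs_a_target, durs_b_target, target_sides=("left",
                                                              "right")):
    """Two eple-fot matching trials with prescribed post-naming dwell.

    ``durs_a_target`` = (ms on A, ms on B) when A (eple) is the target;
    ``durs_b_target`` likewise when B (fot) is the target.  Pre-naming
    looking is split evenly so screening-style preconditions hold.
    """
    t1 = make_trial(trial_id="p01_t01", target_word="eple", heard_word="eple",
                    target_side=target_sides[0])
    t2 = make_trial(trial_id="p01_t02", target_word="fot", heard_word="fot",
                    target_side=target_sides[1], trial_index=2)
    segs1 = [(0, 1000, "target"), (1000, 2000, "distractor"),
             (2367, 2367 + durs_a_target[0], "target"),
             (2367 + durs_a_target[0],
              2367 + durs_a_target[0] + durs_a_target[1], "distractor")]
    # in trial 2 the pictures swap roles: looks at A are distractor looks
    segs2 = [(0, 1000, "target"), (1000, 2000, "distractor"),
             (2367, 2367 + durs_b_target[0], "distractor"),
             (2367 + durs_b_target[0],
              2367 + durs_b_target[0] + durs_b_target[1], "target")]
    gaze = pd.concat([segments_to_gaze(t1, segs1, hz=200),
                      segments_to_gaze(t2, segs2, hz=200)],
                     ignore_index=True)
    return pd.concat([t1, t2], ignore_index=True), gaze


class TestPairScore:
    def test_hand_arithmetic(self):
        # A target: 1.2 s on A, 0.8 s on B -> P_A = 0.6
        # B target: 0.9 s on A, 2.1 s on B -> P_A = 0.3; score = 0.3
        trials, gaze = _pair_fixture((1200, 800), (900, 2100))
        scores = pair_scores(trials, gaze)
        assert len(scores) == 1
        assert scores["score"].iloc[0] == pytest.approx(0.3, abs=0.01)
        assert pair_difference_score(trials.iloc[[0]], trials.iloc[[1]],
                                     gaze) == pytest.approx(0.3, abs=0.01)

    def test_identical_distributions_give_zero(self):
        trials, gaze = _pair_fixture((1000, 1000), (1000, 1000))
        scores = pair_scores(trials, gaze)
        assert scores["score"].iloc[0] == pytest.approx(0.0, abs=0.01)

    def test_perspective_symmetry(self):
        # relabelling which member of the pair is "A" leaves the score alone:
        # swap the roles of the two trials
        trials, gaze = _pair_fixture((1200, 800), (900, 2100))
        swapped = trials.iloc[[1, 0]].reset_index(drop=True)
        s1 = pair_scores(trials, gaze)["score"].iloc[0]
        s2 = pair_scores(swapped, gaze)["score"].iloc[0]
        assert s1 == pytest.approx(s2, abs=1e-9)

    def test_incomplete_pair_discarded(self):
        trials, gaze = _pair_fixture((1200, 800), (900, 2100))
        only_one = trials.iloc[[0]]
        assert len(pair_scores(only_one, gaze)) == 0

    def test_zero_aoi_time_is_undefined(self):
        t1 = make_trial(trial_id="p01_t01", target_word="eple")
        t2 = make_trial(trial_id="p01_t02", target_word="fot",
                        target_side="right")
        gaze = pd.concat([
            segments_to_gaze(t1, [(0, 5500, "away")], hz=100),
            segments_to_gaze(t2, [(0, 5500, "target")], hz=100)])
        trials = pd.concat([t1, t2], ignore_index=True)
        assert len(pair_scores(trials, gaze)) == 0
        with pytest.raises(ValueError):
            pair_difference_score(t1, t2, gaze)

    def test_scores_bounded_and_log_safe(self, clean_cohort, screened):
        scores = pair_scores(screened.included_trials(), clean_cohort.gaze)
        assert scores["score"].between(-1, 1).all()
        assert (np.log(scores["score"] + 2) >= 0).all()


class TestAggregation:
    def test_mean_by_group(self):
        scores = pd.DataFrame({
            "participant_id": ["p01", "p01", "p02"],
            "pair_id": ["a", "b", "a"],
            "condition": ["context"] * 3,
            "trial_type": ["matching"] * 3,
            "score": [0.2, 0.4, -0.1]})
        subj = aggregate_scores(scores, by="subject")
        assert subj.set_index("participant_id").loc["p01", "score"] \
            == pytest.approx(0.3)
        item = aggregate_scores(scores, by="item")
        assert item.set_index("pair_id").loc["a", "score"] \
            == pytest.approx(0.05)

    def test_single_score_passes_through(self):
        scores = pd.DataFrame({"participant_id": ["p01"], "pair_id": ["a"],
                               "condition": ["context"],
                               "trial_type": ["matching"], "score": [0.7]})
        assert aggregate_scores(scores)["score"].iloc[0] == 0.7

    def test_by_item_has_four_frequency_pairs(self, clean_cohort, screened):
        scores = pair_scores(screened.included_trials(), clean_cohort.gaze)
        item = aggregate_scores(scores, by="item")
        freq = item[(item["condition"] == "frequency")
                    & (item["trial_type"] == "matching")]
        assert len(freq) == 4

    def test_empty_input_empty_output(self):
        empty = pd.DataFrame(columns=["participant_id", "pair_id",
                                      "condition", "trial_type", "score"])
        assert len(aggregate_scores(empty)) == 0


class TestBaselineCorrected:
    def test_identical_pre_post_is_zero(self):
        t = make_trial()
        gaze = segments_to_gaze(t, [(0, 1000, "target"),
                                    (1000, 2000, "distractor"),
                                    (2367, 3900, "target"),
                                    (3900, 5433, "distractor")], hz=200)
        out = baseline_corrected(t, gaze)
        assert out["value"].iloc[0] == pytest.approx(0.0, abs=0.02)

    def test_even_pre_all_target_post_is_one(self):
        t = make_trial()
        gaze = segments_to_gaze(t, [(0, 1000, "target"),
                                    (1000, 2000, "distractor"),
                                    (2367, 5500, "target")], hz=200)
        out = baseline_corrected(t, gaze)
        assert out["value"].iloc[0] == pytest.approx(1.0, abs=0.02)

    def test_undefined_window_dropped(self):
        t = make_trial()
        gaze = segments_to_gaze(t, [(0, 2000, "away"),
                                    (2367, 5500, "target")], hz=200)
        assert len(baseline_corrected(t, gaze)) == 0

    def test_bounds(self, clean_cohort, screened):
        inc = screened.included_trials()
        out = baseline_corrected(inc[inc["trial_type"] == "matching"],
                                 clean_cohort.gaze)
        assert out["value"].between(-2, 2).all()


class TestBinnedSeries:
    def test_transform_values(self):
        assert arcsinsqrt(0.5) == pytest.approx(np.pi / 4)
        assert arcsinsqrt(0.0) == 0.0
        assert arcsinsqrt(1.0) == pytest.approx(np.pi / 2)
        assert CHANCE_TRANSFORMED == pytest.approx(np.pi / 4)
        with pytest.raises(ValueError):
            arcsinsqrt(1.5)

    def test_hand_computed_bin(self):
        # in the bin [650, 700) ms after onset (absolute [2650, 2700)):
        # target dwell [2650, 2680), distractor [2680, 2700) -> 30/50 = 0.6
        t = make_trial()
        gaze = segments_to_gaze(t, [(0, 2000, "target"),
                                    (2000, 2680, "target"),
                                    (2680, 3000, "distractor"),
                                    (3000, 5500, "away")], hz=200)
        series = binned_target_proportion(t, gaze)
        k = int(np.flatnonzero(series.bin_starts_ms == 650.0)[0])
        assert series.values[0, k] == pytest.approx(0.6, abs=0.02)

    def test_missing_bins_stay_missing(self):
        t = make_trial()
        gaze = segments_to_gaze(t, [(0, 2000, "target"),
                                    (3000, 5500, "away")], hz=200)
        series = binned_target_proportion(t, gaze)
        k = int(np.flatnonzero(series.bin_starts_ms == 1500.0)[0])
        assert np.isnan(series.values[0, k])  # away-only bin
        pre = series.bin_starts_ms < 0
        assert np.all(series.values[0, pre][:-1] == 1.0)

    def test_grid_uniform_and_bounded(self, clean_cohort, screened):
        series = binned_target_proportion(screened.included_trials(),
                                          clean_cohort.gaze)
        assert np.allclose(np.diff(series.bin_starts_ms), 50.0)
        assert series.bin_starts_ms[0] == -2000.0
        vals = series.values[~np.isnan(series.values)]
        assert ((vals >= 0) & (vals <= 1)).all()
        trans = series.transformed
        ok = ~np.isnan(trans)
        assert ((trans[ok] >= 0) & (trans[ok] <= np.pi / 2 + 1e-9)).all()

    def test_participant_average_skips_missing(self):
        t1 = make_trial(trial_id="p01_t01")
        t2 = make_trial(trial_id="p01_t02", trial_index=2)
        gaze = pd.concat([
            segments_to_gaze(t1, [(0, 5500, "target")], hz=100),
            segments_to_gaze(t2, [(0, 2000, "target"),
                                  (2000, 5500, "away")], hz=100)])
        trials = pd.concat([t1, t2], ignore_index=True)
        series = binned_target_proportion(trials, gaze)
        ps = participant_series(series, condition="context",
                                trial_type="matching")
        post = series.bin_starts_ms >= 0
        # trial 2 is missing post-naming, so the average equals trial 1 (1.0)
        assert np.nanmin(ps.values[0, post][:-1]) == pytest.approx(1.0)
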