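import numpy as np
import pandas as pd
import pytest

from iplgaze import AOILayout, fixture_cohort, load_packaged_stimuli
from iplgaze.io import TRIAL_COLUMNS

LAYOUT = AOILayout()


def make_trial(trial_id="p01_t01", participant_id="p01", condition="context",
               trial_type="matching", pair_id="eple-fot", target_word="eple",
               heard_word=None, target_side="left", word_onset_ms=2000.0,
               end_ms=5500.0, experimenter_flag=0, block=1, trial_index=1,
               list_id=1) -> pd.DataFrame:
    """One-row trial sheet with sensible defaults."""
    row = dict(participant_id=participant_id, trial_id=trial_id, block=block,
               trial_index=trial_index, condition=condition,
               trial_type=trial_type, pair_id=pair_id,
               target_word=target_word,
               heard_word=heard_word or target_word,
               target_side=target_side, word_onset_ms=word_onset_ms,
               end_ms=end_ms, experimenter_flag=experimenter_flag,
               list_id=list_id)
    return pd.DataFrame([row])[TRIAL_COLUMNS]


def segments_to_gaze(trial, segments, hz=200.0) -> pd.DataFrame:
    """Deterministic gaze stream from hand-placed dwell bouts.

    ``segments`` is a list of (start_ms, end_ms, label) with label in
    {target, distractor, away, invalid}; times outside any segment emit no
    samples.  Coordinates are the AOI centres resolved via the trial's
    target side.
    """
    row = trial.iloc[0]
    tgt_left = row["target_side"] == "left"
    pos = {
        "target": LAYOUT.left_center_px if tgt_left else LAYOUT.right_center_px,
        "distractor": (LAYOUT.right_center_px if tgt_left
                       else LAYOUT.left_center_px),
        "away": (960.0, 540.0),
        "invalid": (np.nan, np.nan),
    }
    dt = 1000.0 / hz
    recs = []
    for start, end, label in segments:
        for t in np.arange(start, end - 1e-9, dt):
            x, y = pos[label]
            recs.append((row["participant_id"], row["trial_id"], t, x, y,
                         int(label != "invalid")))
    return pd.DataFrame(recs, columns=["participant_id", "trial_id", "t_ms",
                                       "x_px", "y_px", "valid"])


def full_familiarity(participant_ids, age_days=220) -> pd.DataFrame:
    """Questionnaire table rating every stimulus word as used (5)."""
    words = list(load_packaged_stimuli()["word"])
    rows = []
    for pid in participant_ids:
        for w in words:
            rows.append((pid, age_days, 1, w, 5, 0))
    return pd.DataFrame(rows, columns=["participant_id", "age_days",
                                       "list_id", "word", "familiarity",
                                       "cdi_understands"])


@pytest.fixture(scope="session")
def stimuli():
    return load_packaged_stimuli()


@pytest.fixture(scope="session")
def clean_cohort():
    """Four-infant near-lossless cohort reused across the suite."""
    return fixture_cohort(n_infants=4, seed=2007)


@pytest.fixture(scope="session")
def screened(clean_cohort):
    from iplgaze import screen_trials

    report = screen_trials(clean_cohort.trials, clean_cohort.gaze,
                           clean_cohort.questionnaires)
    return report
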