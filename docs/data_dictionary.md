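# Data dictionary

All inputs are plain text. Column names are fixed; extra columns are
carried through untouched.

## Gaze export — tab-separated (`gaze.tsv`)

One row per eye-tracker sample.

| column | type | meaning |
| --- | --- | --- |
| participant_id | str | infant identifier |
| trial_id | str | trial identifier, unique within the file |
| t_ms | float ≥ 0 | time since trial start, ms |
| x_px | float | horizontal gaze position, px, origin top-left |
| y_px | float | vertical gaze position, px |
| valid | 0/1 | tracker validity; invalid samples count as `neither` |

Invalid samples may have empty/NaN coordinates. Samples must be
time-ordered within a trial (the readers re-sort if not).

## Trial sheet — CSV (`trials.csv`)

One row per trial.

| column | type | meaning |
| --- | --- | --- |
| participant_id, trial_id | str | keys matching the gaze export |
| block | int | experimental block (1, 2) |
| trial_index | int | presentation order within the session |
| condition | context / frequency / control | |
| trial_type | matching / related / control | |
| pair_id | str | picture pair (e.g. `eple-fot`), `control-*` for controls |
| target_word | str | the *pictured* object whose AOI is the target |
| heard_word | str | the word in the carrier sentence (equals target_word on matching trials) |
| target_side | left / right | side of the target picture |
| word_onset_ms | float | target-word onset in trial time; for the shared-onset pair this is the disambiguating-phoneme onset (metadata responsibility) |
| end_ms | float | trial end; ≥ word_onset_ms + 3500 for experimental trials |
| experimenter_flag | 0/1 | lab-log error flag; 1 excludes the trial |
| list_id | int | counterbalancing list |

## Questionnaires — CSV (`questionnaires.csv`)

Long format, one row per (participant, word).

| column | type | meaning |
| --- | --- | --- |
| participant_id | str | |
| age_days | int | age at test (repeated per row) |
| list_id | int | assigned list (repeated per row) |
| word | str | stimulus word |
| familiarity | 0–5 | parental use rating; 0 = never used |
| cdi_understands | 0/1 | CDI "understands" flag |

## Stimulus table — CSV (packaged, `iplgaze/data/stimulus_table.csv`)

| column | type | meaning |
| --- | --- | --- |
| condition | context / frequency | |
| pair_id | str | picture pair the word belongs to |
| role | referent / related | pictured-object label vs related cue word |
| word | str | Norwegian word |
| english | str | gloss |
| frequency | float or empty | CDS corpus count |
| related_to | str | for related words: the referent they substitute for |

## Truth sidecar — JSON (`truth.json`, simulator output only)

Per-participant age/list/random intercept, per-trial injected δ and
dropout flag, per-pair offsets, and the generating config. **No analysis
stage reads this file**; it exists so tests can compare recovered
quantities against ground truth.
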