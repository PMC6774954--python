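"""Synthetic gaze-cohort generator.

Emulates a two-picture preferential-looking study: each infant contributes
two blocks (context / frequency condition) of 16 trials -- 8 matching and
8 related per condition, built from 4 word pairs per condition with fully
counterbalanced sides -- plus 4 single-picture control trials, together with
a parental questionnaire (age, word familiarity 0-5, CDI "understands"
flags).

Gaze is simulated as area-of-interest (AOI) dwell bouts with exponential
durations rather than a full oculomotor model: the analysis pipeline only
consumes AOI dwell, so richer kinematics would add nothing testable.  Before
the word becomes informative the two pictures are fixated with equal
probability; from 367 ms after target-word onset the target-AOI occupancy is
shifted to 0.5 + delta, where delta is the injected naming-locked preference
for that (condition, trial type) cell, optionally with a linear age slope
and mean-zero per-infant / per-pair heterogeneity.

Everything the generator knows but the analysis must not see (injected
deltas, random intercepts, planted ages) is emitted in a separate
``SyntheticTruth`` sidecar that no analysis stage reads.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (AOILayout, QUESTIONNAIRE_COLUMNS, TRIAL_COLUMNS,
                 load_packaged_stimuli, write_gaze_table,
                 write_questionnaires, write_trial_sheet)


class ConfigurationError(ValueError):
    """Invalid simulator configuration (probability, delta, duration...)."""


@dataclass(frozen=True)
class Missingness:
    """Data-loss model.

    p_trial_dropout: probability a trial yields no usable gaze at all
    (infant never oriented to the screen).  p_sample_loss: i.i.d. per-sample
    track loss (blinks, reflections).  fussiness_hazard_per_ms: constant
    hazard of the infant quitting the trial; all later samples are lost.
    """

    p_trial_dropout: float = 0.10
    p_sample_loss: float = 0.08
    fussiness_hazard_per_ms: float = 3e-5

    def __post_init__(self):
        for name in ("p_trial_dropout", "p_sample_loss"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.fussiness_hazard_per_ms < 0:
            raise ConfigurationError("fussiness hazard must be >= 0")


@dataclass(frozen=True)
class EffectSpec:
    """Injected naming-locked preference shifts, in proportion units.

    ``delta`` maps (condition, trial_type) to the base shift of post-naming
    target occupancy away from 0.5; ``age_slope_per_day`` adds a linear age
    trend (centred at ``age_center_days``).  ``sd_infant`` / ``sd_pair`` are
    mean-zero normal heterogeneity shared within an infant / a word pair,
    the ground truth behind the analysis model's random intercepts.
    """

    delta: dict = field(default_factory=lambda: {
        ("context", "matching"): 0.02, ("frequency", "matching"): 0.02,
        ("context", "related"): 0.0, ("frequency", "related"): 0.0})
    age_slope_per_day: dict = field(default_factory=lambda: {
        ("context", "matching"): 0.003, ("frequency", "matching"): 0.003,
        ("context", "related"): 0.0, ("frequency", "related"): 0.0})
    age_center_days: float = 229.0
    sd_infant: float = 0.03
    sd_pair: float = 0.02

    @classmethod
    def null(cls) -> "EffectSpec":
        """All injected effects zero (heterogeneity kept, mean zero)."""
        zero = {(c, t): 0.0 for c in ("context", "frequency")
                for t in ("matching", "related")}
        return cls(delta=dict(zero), age_slope_per_day=dict(zero))

    def delta_for(self, condition, trial_type, age_days) -> float:
        base = self.delta.get((condition, trial_type), 0.0)
        slope = self.age_slope_per_day.get((condition, trial_type), 0.0)
        return base + slope * (age_days - self.age_center_days)


@dataclass(frozen=True)
class FamiliaritySpec:
    """Parental word-familiarity ratings (0 = never used ... 5) and CDI."""

    p_never: float = 0.04
    rating_probs: tuple = (0.05, 0.10, 0.20, 0.30, 0.35)  # ratings 1..5
    p_cdi_understands: float = 0.20

    def __post_init__(self):
        if not 0 <= self.p_never <= 1 or not 0 <= self.p_cdi_understands <= 1:
            raise ConfigurationError("familiarity probabilities outside [0, 1]")
        if not np.isclose(sum(self.rating_probs), 1.0):
            raise ConfigurationError("rating_probs must sum to 1")


@dataclass(frozen=True)
class CohortConfig:
    """Full recipe for one synthetic cohort.

    The default sampling rate is 60 Hz, a desk-scale stand-in for the
    300 Hz hardware; every downstream computation is time-weighted and
    therefore rate-agnostic.  Trial timing follows the study design: 2000 ms
    of pre-naming exposure, trial end 3500 ms after target-word onset
    (total about 5.5 s).
    """

    n_infants: int = 50
    age_range_days: tuple[int, int] = (184, 274)
    n_lists: int = 2
    sampling_hz: float = 60.0
    trial_layout: dict = field(default_factory=lambda: {
        "matching": 8, "related": 8, "control": 4})
    effect_spec: EffectSpec = field(default_factory=EffectSpec)
    missingness: Missingness = field(default_factory=Missingness)
    familiarity_spec: FamiliaritySpec = field(default_factory=FamiliaritySpec)
    word_onset_ms: float = 2000.0
    trial_end_ms: float = 5500.0
    mean_dwell_ms: float = 800.0
    p_away: float = 0.25
    control_p_away: float = 0.90       # pre-naming: object alone on screen
    control_p_away_post: float = 0.50  # after the prompt infants re-orient
    control_target_pref: float = 0.93
    left_bias: float = 0.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.age_range_days
        if lo > hi or lo < 0:
            raise ConfigurationError("invalid age range")
        if self.n_infants < 1 or self.n_lists < 1:
            raise ConfigurationError("need at least one infant and one list")
        if self.sampling_hz <= 0 or self.mean_dwell_ms <= 0:
            raise ConfigurationError("rate and dwell must be positive")
        if self.trial_end_ms < self.word_onset_ms + 3500.0:
            raise ConfigurationError("trial must last >= onset + 3500 ms")
        for key in ("matching", "related"):
            if self.trial_layout.get(key, 0) not in (0, 8):
                raise ConfigurationError(
                    f"{key} count per condition must be 0 or 8 "
                    "(full counterbalanced cells)")
        if self.trial_layout.get("control", 0) not in (0, 4):
            raise ConfigurationError("control count must be 0 or 4")
        for p in (self.p_away, self.control_p_away, self.control_p_away_post,
                  self.control_target_pref):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("probabilities must lie in [0, 1]")
        for (cond, ttype), d in self.effect_spec.delta.items():
            if not -0.5 <= d <= 0.5:
                raise ConfigurationError(
                    f"delta for {(cond, ttype)} outside [-0.5, 0.5]")


@dataclass
class SyntheticTruth:
    """Ground truth kept out of the analysis path (leak-free sidecar)."""

    participants: pd.DataFrame   # participant_id, age_days, list_id, u_infant
    trial_deltas: pd.DataFrame   # participant_id, trial_id, delta
    pair_offsets: pd.DataFrame   # pair_id, v_pair
    config: CohortConfig

    def to_json(self) -> str:
        cfg = dataclasses.asdict(self.config)
        cfg["effect_spec"]["delta"] = {
            f"{c}/{t}": v for (c, t), v in self.config.effect_spec.delta.items()}
        cfg["effect_spec"]["age_slope_per_day"] = {
            f"{c}/{t}": v
            for (c, t), v in self.config.effect_spec.age_slope_per_day.items()}
        return json.dumps({
            "participants": self.participants.to_dict(orient="list"),
            "trial_deltas": self.trial_deltas.to_dict(orient="list"),
            "pair_offsets": self.pair_offsets.to_dict(orient="list"),
            "config": cfg}, indent=1, sort_keys=True)


@dataclass
class CohortData:
    """One simulated study: the three analysis inputs plus the truth sidecar."""

    gaze: pd.DataFrame
    trials: pd.DataFrame
    questionnaires: pd.DataFrame
    truth: SyntheticTruth

    def write(self, outdir) -> dict:
        """Write gaze.tsv, trials.csv, questionnaires.csv and truth.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"gaze": outdir / "gaze.tsv", "trials": outdir / "trials.csv",
                 "questionnaires": outdir / "questionnaires.csv",
                 "truth": outdir / "truth.json"}
        write_gaze_table(self.gaze, paths["gaze"])
        write_trial_sheet(self.trials, paths["trials"])
        write_questionnaires(self.questionnaires, paths["questionnaires"])
        paths["truth"].write_text(self.truth.to_json())
        return {k: str(v) for k, v in paths.items()}


# --------------------------------------------------------------------------
# Trial-sheet construction (counterbalancing)
# --------------------------------------------------------------------------

_SENTENCE_FRAMES = 4  # distinct carrier sentences, rotated across trials

CONTROL_ITEMS = (("hus", "house"), ("tre", "tree"))


def _pair_trials(pair_id, condition, words, related, list_id):
    """The four trials of one picture pair, sides fully counterbalanced.

    Within each trial type every object appears once on the left and once on
    the right; each object is the target once per side across trial types.
    List 2 mirrors all sides.
    """
    a, b = words           # referent words; picture pair is (a, b)
    ra, rb = related       # related words mapped to a and b respectively
    flip = list_id == 2
    side = lambda s: {"left": "right", "right": "left"}[s] if flip else s
    return [
        dict(condition=condition, trial_type="matching", pair_id=pair_id,
             target_word=a, heard_word=a, target_side=side("left")),
        dict(condition=condition, trial_type="matching", pair_id=pair_id,
             target_word=b, heard_word=b, target_side=side("left")),
        dict(condition=condition, trial_type="related", pair_id=pair_id,
             target_word=a, heard_word=ra, target_side=side("right")),
        dict(condition=condition, trial_type="related", pair_id=pair_id,
             target_word=b, heard_word=rb, target_side=side("right")),
    ]


def _pair_structures(stimuli: pd.DataFrame) -> dict:
    """condition -> [(pair_id, referent words, matched related words)]."""
    out = {}
    for cond, sub in stimuli.groupby("condition"):
        entries = []
        for pair_id in sub["pair_id"].unique():
            ref = sub[(sub["pair_id"] == pair_id) & (sub["role"] == "referent")]
            rel = sub[(sub["pair_id"] == pair_id) & (sub["role"] == "related")]
            words = list(ref["word"])
            related = [rel.loc[rel["related_to"] == w, "word"].iloc[0]
                       for w in words]
            entries.append((pair_id, words, related))
        out[cond] = entries
    return out


def build_trial_sheet(participant_id: str, list_id: int, rng,
                      config: CohortConfig,
                      stimuli: pd.DataFrame | None = None,
                      structures: dict | None = None) -> pd.DataFrame:
    """Pseudo-randomised 2-block trial sheet for one infant."""
    if structures is None:
        stimuli = stimuli if stimuli is not None else load_packaged_stimuli()
        structures = _pair_structures(stimuli)
    rows = _trial_rows(participant_id, list_id, rng, config, structures)
    return pd.DataFrame(rows)[TRIAL_COLUMNS]


def _trial_rows(participant_id, list_id, rng, config, structures) -> list:
    layout = config.trial_layout
    conditions = list(rng.permutation(["context", "frequency"]))
    rows = []
    for block_i, cond in enumerate(conditions, start=1):
        block_rows = []
        for pair_id, words, related in structures[cond]:
            for tr in _pair_trials(pair_id, cond, words, related, list_id):
                if layout.get(tr["trial_type"], 0):
                    block_rows.append(tr)
        order = rng.permutation(len(block_rows))
        block_rows = [block_rows[i] for i in order]
        # control trials after every eighth experimental trial
        if layout.get("control", 0):
            for k, pos in enumerate((8, len(block_rows) + 1)):
                item, _english = CONTROL_ITEMS[(block_i - 1 + k) % 2]
                sides = ["left", "right"] if list_id % 2 else ["right", "left"]
                block_rows.insert(min(pos + k, len(block_rows)), dict(
                    condition="control", trial_type="control",
                    pair_id=f"control-{item}", target_word=item,
                    heard_word=item, target_side=sides[k]))
        rows += [dict(r, block=block_i) for r in block_rows]
    for i, r in enumerate(rows):
        r.update(participant_id=participant_id,
                 trial_id=f"{participant_id}_t{i + 1:02d}",
                 trial_index=i + 1, word_onset_ms=config.word_onset_ms,
                 end_ms=config.trial_end_ms, experimenter_flag=0,
                 list_id=list_id)
    return rows


# --------------------------------------------------------------------------
# Gaze stream simulation
# --------------------------------------------------------------------------

def _simulate_gaze_block(n_trials, end_ms, switch_ms, pref_pre,
                         pref_post, p_away_pre, p_away_post, target_left,
                         rate_hz, dwell_ms, left_bias, p_sample_loss, hazard,
                         dropout_mask, rng, layout: AOILayout):
    """Vectorised dwell-bout gaze simulation for ``n_trials`` same-length trials.

    Returns (t_ms tiled per trial, x, y, valid) flat arrays in trial order.
    States alternate between left AOI, right AOI and away (midline gap);
    bout durations are exponential with mean ``dwell_ms``; a fresh bout
    starts at ``switch_ms`` where the target preference changes.
    """
    dt = 1000.0 / rate_hz
    t = np.arange(0.0, end_ms, dt)
    S = len(t)

    def _phase(t0, t1, pref, p_away):
        span = t1 - t0
        k = int(np.ceil(span / dwell_ms * 2.5)) + 6
        d = rng.exponential(dwell_ms, size=(n_trials, k))
        edges = t0 + np.cumsum(d, axis=1)
        # guarantee coverage: final synthetic bout extends past the phase
        edges[:, -1] = t1 + 1.0
        u = rng.random((n_trials, k))
        on = u >= p_away[:, None]
        u2 = rng.random((n_trials, k))
        p_tgt = np.broadcast_to(pref[:, None], (n_trials, k))
        p_left_on = np.where(target_left[:, None], p_tgt, 1.0 - p_tgt)
        p_left_on = np.clip(p_left_on + left_bias, 0.0, 1.0)
        state = np.where(on, np.where(u2 < p_left_on, 1, 2), 0)
        return edges, state

    e1, s1 = _phase(0.0, switch_ms, pref_pre, p_away_pre)
    e2, s2 = _phase(switch_ms, end_ms, pref_post, p_away_post)
    e1 = np.minimum(e1, switch_ms)  # phase-1 bouts never leak past the switch
    edges = np.concatenate([e1, e2], axis=1)
    states = np.concatenate([s1, s2], axis=1)
    idx = (t[None, :, None] >= edges[:, None, :]).sum(axis=2)
    state = np.take_along_axis(states, idx, axis=1)  # (n_trials, S)

    lx0, ly0, lx1, ly1 = layout.rect("left")
    rx0, ry0, rx1, ry1 = layout.rect("right")
    m = 40.0  # inset so jitter stays inside the AOI
    ux = rng.random((n_trials, S))
    uy = rng.random((n_trials, S))
    x = np.where(state == 1, lx0 + m + ux * (lx1 - lx0 - 2 * m),
                 np.where(state == 2, rx0 + m + ux * (rx1 - rx0 - 2 * m),
                          lx1 + 20 + ux * (rx0 - lx1 - 40)))
    y = np.where(state == 0, 200 + uy * 680.0,
                 ly0 + m + uy * (ly1 - ly0 - 2 * m))

    valid = rng.random((n_trials, S)) >= p_sample_loss[:, None]
    if np.any(hazard > 0):
        with np.errstate(divide="ignore"):
            scale = np.where(hazard > 0, 1.0 / np.maximum(hazard, 1e-300),
                             np.inf)
        quit_t = np.where(hazard > 0, rng.exponential(1.0, n_trials) * scale,
                          np.inf)
        valid &= t[None, :] < quit_t[:, None]
    valid &= ~dropout_mask[:, None]
    x = np.where(valid, x, np.nan)
    y = np.where(valid, y, np.nan)
    return (np.tile(t, n_trials), x.ravel(), y.ravel(), valid.ravel())


def simulate_trial_gaze(trial_meta, delta: float,
                        missingness: Missingness | None = None,
                        rng=None, *, rate_hz: float = 60.0,
                        mean_dwell_ms: float = 800.0, p_away: float = 0.25,
                        left_bias: float = 0.0,
                        layout: AOILayout | None = None) -> pd.DataFrame:
    """Simulate the gaze stream of a single two-picture trial.

    ``trial_meta`` is a mapping with at least target_side, word_onset_ms and
    end_ms (participant_id / trial_id are carried through if present).  The
    expected target-AOI occupancy is 0.5 before ``word_onset + 367 ms`` and
    ``0.5 + delta`` after, up to sampling error.
    """
    missingness = missingness or Missingness(0.0, 0.0, 0.0)
    rng = rng if rng is not None else np.random.default_rng()
    layout = layout or AOILayout()
    onset = float(trial_meta["word_onset_ms"])
    end = float(trial_meta["end_ms"])
    if not -0.5 <= delta <= 0.5:
        raise ConfigurationError(f"delta={delta} outside [-0.5, 0.5]")
    if end <= 0 or end < onset + 3500.0:
        raise ConfigurationError("trial duration must cover onset + 3500 ms")
    dropout = np.array([rng.random() < missingness.p_trial_dropout])
    t, x, y, valid = _simulate_gaze_block(
        1, end, onset + 367.0,
        np.array([0.5]), np.array([0.5 + delta]), np.array([p_away]),
        np.array([p_away]),
        np.array([trial_meta["target_side"] == "left"]), rate_hz,
        mean_dwell_ms, left_bias,
        np.array([missingness.p_sample_loss]),
        np.array([missingness.fussiness_hazard_per_ms]), dropout, rng, layout)
    return pd.DataFrame({
        "participant_id": trial_meta.get("participant_id", "p00"),
        "trial_id": trial_meta.get("trial_id", "p00_t01"),
        "t_ms": t, "x_px": x, "y_px": y, "valid": valid.astype(int)})


# --------------------------------------------------------------------------
# Whole-cohort simulation
# --------------------------------------------------------------------------

def simulate_cohort(config: CohortConfig,
                    layout: AOILayout | None = None) -> CohortData:
    """Generate a complete synthetic study dataset.

    Deterministic given ``config.seed``: identical configs produce
    byte-identical files.
    """
    rng = np.random.default_rng(config.seed)
    layout = layout or AOILayout()
    stimuli = load_packaged_stimuli()
    eff = config.effect_spec

    lo, hi = config.age_range_days
    n = config.n_infants
    pids = [f"p{i + 1:03d}" for i in range(n)]
    ages = rng.integers(lo, hi + 1, size=n)
    lists = rng.integers(1, config.n_lists + 1, size=n)
    u_infant = rng.normal(0.0, eff.sd_infant, size=n)
    pair_ids = list(stimuli["pair_id"].unique())
    v_pair = dict(zip(pair_ids, rng.normal(0.0, eff.sd_pair, len(pair_ids))))

    structures = _pair_structures(stimuli)
    rows_per = [_trial_rows(pid, int(lists[i]), rng, config, structures)
                for i, pid in enumerate(pids)]
    trials = pd.DataFrame([r for rows in rows_per for r in rows],
                          columns=TRIAL_COLUMNS)
    sheets = rows_per  # per-infant trial counts for repeats below

    # per-trial injected deltas (experimental) / control preference
    is_ctrl = (trials["trial_type"] == "control").to_numpy()
    age_per_trial = np.repeat(ages, [len(s) for s in sheets])
    u_per_trial = np.repeat(u_infant, [len(s) for s in sheets])
    delta = np.zeros(len(trials))
    for (cond, ttype), grp in trials.groupby(["condition", "trial_type"]):
        if ttype == "control":
            continue
        i = grp.index.to_numpy()
        base = np.array([eff.delta_for(cond, ttype, a)
                         for a in age_per_trial[i]])
        vp = np.array([v_pair[p] for p in grp["pair_id"]])
        delta[i] = np.clip(base + u_per_trial[i] + vp, -0.45, 0.45)

    pref_pre = np.where(is_ctrl, config.control_target_pref, 0.5)
    pref_post = np.where(is_ctrl, config.control_target_pref, 0.5 + delta)
    # infants re-orient to the named control object: away time drops after
    # the prompt, so every engaged infant shows post-naming target looking
    p_away_pre = np.where(is_ctrl, config.control_p_away, config.p_away)
    p_away_post = np.where(is_ctrl, config.control_p_away_post,
                           config.p_away)
    miss = config.missingness
    dropout = rng.random(len(trials)) < miss.p_trial_dropout
    t, x, y, valid = _simulate_gaze_block(
        len(trials),
        float(config.trial_end_ms), float(config.word_onset_ms + 367.0),
        pref_pre, pref_post, p_away_pre, p_away_post,
        (trials["target_side"] == "left").to_numpy(), config.sampling_hz,
        config.mean_dwell_ms, config.left_bias,
        np.full(len(trials), miss.p_sample_loss),
        np.full(len(trials), miss.fussiness_hazard_per_ms),
        dropout, rng, layout)
    S = len(t) // len(trials)
    gaze = pd.DataFrame({
        "participant_id": np.repeat(trials["participant_id"].to_numpy(), S),
        "trial_id": np.repeat(trials["trial_id"].to_numpy(), S),
        "t_ms": t, "x_px": x, "y_px": y, "valid": valid.astype(int)})

    # questionnaires: one row per (participant, word)
    words = list(stimuli["word"])
    fam = config.familiarity_spec
    never = rng.random((n, len(words))) < fam.p_never
    ratings = 1 + rng.choice(5, size=(n, len(words)), p=fam.rating_probs)
    ratings = np.where(never, 0, ratings)
    cdi = (rng.random((n, len(words))) < fam.p_cdi_understands).astype(int)
    questionnaires = pd.DataFrame({
        "participant_id": np.repeat(pids, len(words)),
        "age_days": np.repeat(ages, len(words)),
        "list_id": np.repeat(lists, len(words)),
        "word": words * n,
        "familiarity": ratings.ravel(),
        "cdi_understands": cdi.ravel()})[QUESTIONNAIRE_COLUMNS]

    truth = SyntheticTruth(
        participants=pd.DataFrame({"participant_id": pids, "age_days": ages,
                                   "list_id": lists, "u_infant": u_infant}),
        trial_deltas=pd.DataFrame({
            "participant_id": trials["participant_id"],
            "trial_id": trials["trial_id"],
            "delta": np.where(is_ctrl, np.nan, delta),
            "dropout": dropout}),
        pair_offsets=pd.DataFrame({"pair_id": pair_ids,
                                   "v_pair": [v_pair[p] for p in pair_ids]}),
        config=config)
    return CohortData(gaze=gaze, trials=trials,
                      questionnaires=questionnaires, truth=truth)


def fixture_cohort(n_infants: int = 4, seed: int = 20_07,
                   **overrides) -> CohortData:
    """Small clean cohort used throughout the test suite."""
    cfg = CohortConfig(n_infants=n_infants, seed=seed,
                       missingness=Missingness(0.0, 0.02, 0.0), **overrides)
    return simulate_cohort(cfg)
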