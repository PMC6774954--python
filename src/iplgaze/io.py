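"""Tabular gaze formats, screen/AOI geometry, and analysis-window slicing.

The package works on three plain-text inputs -- a tab-separated gaze export
(one row per eye-tracker sample), a CSV trial sheet, and a CSV parental
questionnaire file -- plus a packaged stimulus table describing the word
pairs, their conditions and child-directed-speech (CDS) frequencies.

Coordinates are screen pixels with the origin at the top-left corner.  Areas
of interest (AOIs) are half-open rectangles ``[x0, x1) x [y0, y1)``.  All
duration accounting is time-weighted: each gaze sample covers the interval
from its timestamp to the next sample's timestamp, clipped to the analysis
window, so results are invariant to the sampling rate in the dense limit.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

# --------------------------------------------------------------------------
# Column dictionaries (see docs/data_dictionary.md)
# --------------------------------------------------------------------------

GAZE_COLUMNS = ["participant_id", "trial_id", "t_ms", "x_px", "y_px", "valid"]

TRIAL_COLUMNS = [
    "participant_id", "trial_id", "block", "trial_index", "condition",
    "trial_type", "pair_id", "target_word", "heard_word", "target_side",
    "word_onset_ms", "end_ms", "experimenter_flag", "list_id",
]

QUESTIONNAIRE_COLUMNS = [
    "participant_id", "age_days", "list_id", "word", "familiarity",
    "cdi_understands",
]

STIMULUS_COLUMNS = [
    "condition", "pair_id", "role", "word", "english", "frequency",
    "related_to",
]

CONDITIONS = ("context", "frequency")
TRIAL_TYPES = ("matching", "related")
SIDES = ("left", "right")


class ParseError(ValueError):
    """Structured parse failure naming the file and offending column/row."""

    def __init__(self, path, message, column=None, row=None):
        self.path = str(path)
        self.column = column
        self.row = row
        loc = f"{self.path}"
        if row is not None:
            loc += f", row {row}"
        if column is not None:
            loc += f", column '{column}'"
        super().__init__(f"{loc}: {message}")


# --------------------------------------------------------------------------
# Geometry
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AOILayout:
    """Screen geometry for the two-picture display.

    Default AOIs are 800 x 680-pixel rectangles centred in each half of a
    1920 x 1080 screen, i.e. at (480, 540) and (1440, 540).  The pictures
    themselves are smaller; the AOI is the invisible hit rectangle around
    each object.
    """

    screen_px: tuple[int, int] = (1920, 1080)
    aoi_size_px: tuple[int, int] = (800, 680)
    left_center_px: tuple[float, float] = (480.0, 540.0)
    right_center_px: tuple[float, float] = (1440.0, 540.0)

    def __post_init__(self):
        lx0, ly0, lx1, ly1 = self.rect("left")
        rx0, ry0, rx1, ry1 = self.rect("right")
        w, h = self.screen_px
        if not (0 <= lx0 and lx1 <= w and 0 <= ly0 and ly1 <= h):
            raise ValueError("left AOI extends off-screen")
        if not (0 <= rx0 and rx1 <= w and 0 <= ry0 and ry1 <= h):
            raise ValueError("right AOI extends off-screen")
        if lx1 > rx0:
            raise ValueError("left and right AOIs overlap")
        mid = w / 2.0
        if not np.isclose(mid - self.left_center_px[0],
                          self.right_center_px[0] - mid):
            raise ValueError("AOIs are not mirror-symmetric about the midline")
        if not np.isclose(self.left_center_px[1], self.right_center_px[1]):
            raise ValueError("AOIs are not at the same height")

    def rect(self, side: str) -> tuple[float, float, float, float]:
        """Half-open rectangle (x0, y0, x1, y1) of the given side's AOI."""
        cx, cy = self.left_center_px if side == "left" else self.right_center_px
        w, h = self.aoi_size_px
        return (cx - w / 2.0, cy - h / 2.0, cx + w / 2.0, cy + h / 2.0)


def assign_aoi(x_px, y_px, valid, target_side, layout: AOILayout | None = None):
    """Label gaze points as ``target`` / ``distractor`` / ``neither``.

    Vectorised: accepts scalars or equal-length arrays.  Invalid samples and
    points outside both AOIs (including off-screen points) map to
    ``neither``; the function never raises for bad coordinates.
    """
    layout = layout or AOILayout()
    x = np.asarray(x_px, dtype=float)
    y = np.asarray(y_px, dtype=float)
    v = np.asarray(valid).astype(bool)
    side = np.asarray(target_side)
    scalar = x.ndim == 0
    x, y, v = np.atleast_1d(x), np.atleast_1d(y), np.atleast_1d(v)
    side = np.atleast_1d(side)
    if side.size == 1:
        side = np.repeat(side, x.size)

    lx0, ly0, lx1, ly1 = layout.rect("left")
    rx0, ry0, rx1, ry1 = layout.rect("right")
    with np.errstate(invalid="ignore"):
        in_left = (x >= lx0) & (x < lx1) & (y >= ly0) & (y < ly1) & v
        in_right = (x >= rx0) & (x < rx1) & (y >= ry0) & (y < ry1) & v
    target_left = side == "left"
    out = np.full(x.shape, "neither", dtype=object)
    out[in_left & target_left] = "target"
    out[in_left & ~target_left] = "distractor"
    out[in_right & ~target_left] = "target"
    out[in_right & target_left] = "distractor"
    return out.item() if scalar else out


# --------------------------------------------------------------------------
# Analysis windows
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalysisWindows:
    """Trial-relative analysis windows, anchored at the target-word onset.

    * pre-naming: [trial start, word onset)
    * post-naming: [onset + 367 ms, onset + 3500 ms] (3133 ms long)
    * cluster window: [onset - 2000 ms, trial end), binned at 50 ms

    Durations are computed on half-open intervals; the closed right edge of
    the post-naming window is a labelling convention with zero measure.
    """

    post_start_ms: float = 367.0
    post_end_ms: float = 3500.0
    cluster_pre_ms: float = 2000.0
    bin_ms: float = 50.0

    def __post_init__(self):
        if not (0 <= self.post_start_ms < self.post_end_ms):
            raise ValueError("post-naming window is empty or negative")
        if self.bin_ms <= 0 or self.cluster_pre_ms < 0:
            raise ValueError("bin width and cluster margin must be positive")

    @property
    def post_length_ms(self) -> float:
        return self.post_end_ms - self.post_start_ms

    def bounds(self, which: str, word_onset_ms: float, end_ms: float):
        """Absolute (t0, t1) in trial time for a named window."""
        if which == "prenaming":
            return 0.0, float(word_onset_ms)
        if which == "postnaming":
            return (word_onset_ms + self.post_start_ms,
                    word_onset_ms + self.post_end_ms)
        if which == "cluster":
            return word_onset_ms - self.cluster_pre_ms, float(end_ms)
        raise ValueError(f"unknown window {which!r}")


# --------------------------------------------------------------------------
# Readers / writers
# --------------------------------------------------------------------------

def _read_table(path, sep, required: Iterable[str], numeric: Iterable[str]):
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=list(required))
    except Exception as exc:  # malformed file
        raise ParseError(path, f"unreadable table: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(path, "missing required column", column=missing[0])
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            raise ParseError(path, f"unparseable value {df[col][bad].iloc[0]!r}",
                             column=col, row=int(np.flatnonzero(bad)[0]) + 2)
        df[col] = coerced
    return df


def read_gaze_table(path) -> pd.DataFrame:
    """Read a tab-separated gaze export. Empty files yield an empty frame."""
    df = _read_table(path, "\t", GAZE_COLUMNS, ["t_ms", "x_px", "y_px", "valid"])
    if len(df) and (df["t_ms"] < 0).any():
        raise ParseError(path, "negative timestamp", column="t_ms",
                         row=int(np.flatnonzero(df["t_ms"] < 0)[0]) + 2)
    df["valid"] = df["valid"].fillna(0).astype(bool)
    return df[GAZE_COLUMNS] if len(df) else df


def write_gaze_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False,
              columns=[c for c in GAZE_COLUMNS if c in df.columns],
              float_format="%.10g")


def read_trial_sheet(path) -> pd.DataFrame:
    df = _read_table(path, ",", TRIAL_COLUMNS,
                     ["word_onset_ms", "end_ms", "experimenter_flag"])
    for col, allowed in [("trial_type", set(TRIAL_TYPES) | {"control"}),
                         ("target_side", set(SIDES))]:
        if len(df):
            bad = ~df[col].isin(allowed)
            if bad.any():
                raise ParseError(path, f"unknown value {df[col][bad].iloc[0]!r}",
                                 column=col,
                                 row=int(np.flatnonzero(bad)[0]) + 2)
    exp = df[df["trial_type"].isin(TRIAL_TYPES)] if len(df) else df
    if len(exp):
        short = exp["word_onset_ms"] + 3500.0 > exp["end_ms"] + 1e-9
        if short.any():
            raise ParseError(path, "experimental trial shorter than onset+3500 ms",
                             column="end_ms",
                             row=int(exp.index[short][0]) + 2)
    return df


def write_trial_sheet(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def read_questionnaires(path) -> pd.DataFrame:
    """Long-format parental questionnaire: one row per (participant, word)."""
    df = _read_table(path, ",", QUESTIONNAIRE_COLUMNS,
                     ["age_days", "familiarity", "cdi_understands"])
    if len(df):
        bad = ~df["familiarity"].between(0, 5)
        if bad.any():
            raise ParseError(path, "familiarity rating outside 0-5",
                             column="familiarity",
                             row=int(np.flatnonzero(bad)[0]) + 2)
    return df


def write_questionnaires(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def read_stimulus_table(path) -> pd.DataFrame:
    df = _read_table(path, ",", STIMULUS_COLUMNS, ["frequency"])
    if len(df) and (df["frequency"].dropna() < 0).any():
        raise ParseError(path, "negative CDS frequency", column="frequency")
    for (pair, role), grp in df.groupby(["pair_id", "role"]):
        if len(grp) != 2:
            raise ParseError(path, f"pair {pair!r} has {len(grp)} {role} words "
                                   "(expected exactly 2)", column="pair_id")
    return df


def load_packaged_stimuli() -> pd.DataFrame:
    """The study's 32-word stimulus table (8 pairs x {referent, related})."""
    with resources.as_file(resources.files("iplgaze") / "data"
                           / "stimulus_table.csv") as p:
        return read_stimulus_table(p)


def participant_ages(questionnaires: pd.DataFrame) -> pd.Series:
    """Per-participant age in days from the long questionnaire table."""
    return questionnaires.groupby("participant_id")["age_days"].first()


# --------------------------------------------------------------------------
# Looking-time accounting
# --------------------------------------------------------------------------

def _ensure_trialwise_sorted(g: pd.DataFrame) -> pd.DataFrame:
    """Sort by (trial, time) only when some trial's samples are out of order."""
    if len(g) < 2:
        return g
    t = g["t_ms"].to_numpy(float)
    trial = g["trial_id"].to_numpy()
    ok = np.all((np.diff(t) >= 0) | (trial[1:] != trial[:-1]))
    if ok:
        return g
    return g.sort_values(["trial_id", "t_ms"], kind="stable",
                         ignore_index=True)


def _sample_intervals(gaze: pd.DataFrame) -> np.ndarray:
    """End time of each sample's coverage interval.

    A sample covers [t, t_next) but never more than the nominal
    inter-sample interval (the median within-trial timestamp difference):
    a recording gap means lost samples, and the time is not credited to the
    AOI of the last sample before the gap.
    """
    t = gaze["t_ms"].to_numpy(float)
    trial = gaze["trial_id"].to_numpy()
    nxt = np.empty_like(t)
    nxt[:-1] = t[1:]
    same = np.empty(len(t), dtype=bool)
    same[:-1] = trial[:-1] == trial[1:]
    same[-1] = False
    if len(t) > 1:
        dts = np.diff(t)[same[:-1]]
        dt = np.median(dts) if len(dts) else 0.0
    else:
        dt = 0.0
    nxt[-1] = t[-1] + dt
    nxt[~same] = t[~same] + dt
    return np.minimum(nxt, t + dt)


def looking_times(trial_gaze: pd.DataFrame, target_side: str,
                  window: tuple[float, float],
                  layout: AOILayout | None = None) -> tuple[float, float, float]:
    """Time-weighted (target, distractor, neither) durations in ``window``.

    Each sample contributes the overlap of its coverage interval with the
    window; samples straddling a boundary are clipped.  Invalid samples count
    as ``neither``.
    """
    out = looking_times_table(
        trial_gaze,
        pd.DataFrame({"trial_id": trial_gaze["trial_id"].unique() if len(trial_gaze) else ["_"],
                      "target_side": target_side,
                      "w0": window[0], "w1": window[1]}),
        layout)
    if not len(out):
        return (0.0, 0.0, 0.0)
    row = out.iloc[0]
    return (float(row["t_target_ms"]), float(row["t_distractor_ms"]),
            float(row["t_neither_ms"]))


def looking_times_table(gaze: pd.DataFrame, trial_windows: pd.DataFrame,
                        layout: AOILayout | None = None) -> pd.DataFrame:
    """Vectorised looking times for many trials at once.

    ``trial_windows`` needs columns trial_id, target_side, w0, w1 (absolute
    trial-time bounds).  Returns one row per requested trial with columns
    t_target_ms / t_distractor_ms / t_neither_ms (zero for trials without
    samples).
    """
    layout = layout or AOILayout()
    tw = trial_windows.reset_index(drop=True)
    if (tw["w1"] < tw["w0"]).any():
        raise ValueError("window end precedes window start")
    if not len(gaze):
        out = tw[["trial_id"]].copy()
        out[["t_target_ms", "t_distractor_ms", "t_neither_ms"]] = 0.0
        return out
    g = _ensure_trialwise_sorted(gaze.merge(tw, on="trial_id", how="inner"))
    t0 = g["t_ms"].to_numpy(float)
    t1 = _sample_intervals(g[["trial_id", "t_ms"]])
    dur = np.clip(np.minimum(t1, g["w1"].to_numpy(float))
                  - np.maximum(t0, g["w0"].to_numpy(float)), 0.0, None)
    label = assign_aoi(g["x_px"], g["y_px"], g["valid"], g["target_side"],
                       layout)
    label = np.atleast_1d(label)
    codes, uniques = pd.factorize(g["trial_id"], sort=False)
    acc = np.zeros((len(uniques), 3))
    for j, name in enumerate(("target", "distractor", "neither")):
        np.add.at(acc[:, j], codes[label == name], dur[label == name])
    res = pd.DataFrame(acc, columns=["t_target_ms", "t_distractor_ms",
                                     "t_neither_ms"])
    res.insert(0, "trial_id", uniques)
    out = tw[["trial_id"]].merge(res, on="trial_id", how="left").fillna(0.0)
    return out


def windows_for_trials(trials: pd.DataFrame, which: str,
                       windows: AnalysisWindows | None = None) -> pd.DataFrame:
    """Build the (trial_id, target_side, w0, w1) frame for a named window."""
    windows = windows or AnalysisWindows()
    onset = trials["word_onset_ms"].to_numpy(float)
    end = trials["end_ms"].to_numpy(float)
    if which == "prenaming":
        w0, w1 = np.zeros_like(onset), onset
    elif which == "postnaming":
        w0 = onset + windows.post_start_ms
        w1 = onset + windows.post_end_ms
    elif which == "cluster":
        w0, w1 = onset - windows.cluster_pre_ms, end
    else:
        raise ValueError(f"unknown window {which!r}")
    if (w1 > end + 1e-9).any() and which == "postnaming":
        raise ValueError("post-naming window extends past trial end")
    return pd.DataFrame({"trial_id": trials["trial_id"].to_numpy(),
                         "target_side": trials["target_side"].to_numpy(),
                         "w0": w0, "w1": w1})
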