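"""Dependent variables: pair difference scores, baseline-corrected looking,
and 50 ms-binned target-proportion time courses.

All proportions condition on AOI time only -- looks that land on neither
picture are excluded from the denominator, matching the definition
P = t_target / (t_target + t_distractor).  The central datum is the
*difference in looking proportion* for a picture pair (A, B): the
proportion of looks at A when A was named minus the proportion of looks at
A when B was named; chance is 0 and the score is bounded in [-1, 1].  The
score is perspective-symmetric because P_B = 1 - P_A in every trial.

When a word was targeted more than once (the design shows each pair twice
per trial type), the surviving presentations are pooled at the
duration level before proportions are formed, yielding exactly one matching
and one related score per pair per infant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (AnalysisWindows, AOILayout, looking_times_table,
                 windows_for_trials)


def arcsinsqrt(p):
    """Variance-stabilising arcsine-square-root transform of a proportion."""
    p = np.asarray(p, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any((p < 0) | (p > 1)):
            raise ValueError("proportion outside [0, 1]")
        return np.arcsin(np.sqrt(p))


CHANCE_TRANSFORMED = float(np.arcsin(np.sqrt(0.5)))  # pi/4


# --------------------------------------------------------------------------
# Pair difference scores
# --------------------------------------------------------------------------

def _post_durations(trials: pd.DataFrame, gaze: pd.DataFrame,
                    windows: AnalysisWindows, layout: AOILayout | None):
    post = looking_times_table(gaze, windows_for_trials(trials, "postnaming",
                                                        windows), layout)
    return trials.reset_index(drop=True).join(
        post[["t_target_ms", "t_distractor_ms"]])


def pair_scores(trials: pd.DataFrame, gaze: pd.DataFrame,
                windows: AnalysisWindows | None = None,
                layout: AOILayout | None = None) -> pd.DataFrame:
    """Difference-in-looking-proportion scores for all screened-in pairs.

    ``trials`` must contain only screened-in experimental trials.  A score
    for (participant, pair, trial_type) is produced only when both pair
    members survive as targets; otherwise the pair is discarded.  Returns a
    tidy frame with columns participant_id, pair_id, condition, trial_type,
    score, n_trials.
    """
    windows = windows or AnalysisWindows()
    if not len(trials):
        return pd.DataFrame(columns=["participant_id", "pair_id", "condition",
                                     "trial_type", "score", "n_trials"])
    d = _post_durations(trials, gaze, windows, layout)
    agg = d.groupby(["participant_id", "pair_id", "condition", "trial_type",
                     "target_word"], as_index=False).agg(
        t_target_ms=("t_target_ms", "sum"),
        t_distractor_ms=("t_distractor_ms", "sum"),
        n=("trial_id", "size"))
    rows = []
    for (pid, pair, cond, ttype), grp in agg.groupby(
            ["participant_id", "pair_id", "condition", "trial_type"]):
        if len(grp) != 2:
            continue  # pair incomplete after screening
        a, b = grp.iloc[0], grp.iloc[1]
        den_a = a["t_target_ms"] + a["t_distractor_ms"]
        den_b = b["t_target_ms"] + b["t_distractor_ms"]
        if den_a <= 0 or den_b <= 0:
            continue  # no AOI looking; should already be screened out
        # P(looks at A | A target) - P(looks at A | A distractor)
        score = a["t_target_ms"] / den_a - b["t_distractor_ms"] / den_b
        rows.append((pid, pair, cond, ttype, score,
                     int(a["n"] + b["n"])))
    return pd.DataFrame(rows, columns=["participant_id", "pair_id",
                                       "condition", "trial_type", "score",
                                       "n_trials"])


def pair_difference_score(trial_a: pd.DataFrame, trial_b: pd.DataFrame,
                          gaze: pd.DataFrame,
                          windows: AnalysisWindows | None = None,
                          layout: AOILayout | None = None) -> float:
    """Score for one pair from its two trials (A target, then B target)."""
    both = pd.concat([trial_a, trial_b], ignore_index=True)
    if both["pair_id"].nunique() != 1 or both["trial_type"].nunique() != 1:
        raise ValueError("trials must share pair_id and trial_type")
    out = pair_scores(both, gaze, windows, layout)
    if not len(out):
        raise ValueError("score undefined: a trial has no AOI looking")
    return float(out["score"].iloc[0])


def aggregate_scores(scores: pd.DataFrame, by: str = "subject",
                     within: tuple = ("condition", "trial_type")
                     ) -> pd.DataFrame:
    """Average pair scores by subject (over pairs) or by item (over subjects)."""
    if not len(scores):
        return scores.copy()
    if by == "subject":
        keys = ["participant_id", *within]
    elif by == "item":
        keys = ["pair_id", *within]
    else:
        raise ValueError("by must be 'subject' or 'item'")
    return scores.groupby(list(keys), as_index=False).agg(
        score=("score", "mean"), n=("score", "size"))


# --------------------------------------------------------------------------
# Baseline-corrected looking
# --------------------------------------------------------------------------

def baseline_corrected(trials: pd.DataFrame, gaze: pd.DataFrame,
                       windows: AnalysisWindows | None = None,
                       layout: AOILayout | None = None) -> pd.DataFrame:
    """(P_target - P_distractor) post-naming minus pre-naming, per trial.

    Bounded in [-2, 2]; rows where either window has no AOI looking are
    dropped (the value is undefined, not zero).
    """
    windows = windows or AnalysisWindows()
    if not len(trials):
        return pd.DataFrame(columns=[*trials.columns, "value"])
    parts = {}
    for which in ("prenaming", "postnaming"):
        lt = looking_times_table(gaze, windows_for_trials(trials, which,
                                                          windows), layout)
        den = (lt["t_target_ms"] + lt["t_distractor_ms"]).to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            diff = np.where(den > 0,
                            (lt["t_target_ms"] - lt["t_distractor_ms"]) / den,
                            np.nan)
        parts[which] = diff
    out = trials.reset_index(drop=True).copy()
    out["value"] = parts["postnaming"] - parts["prenaming"]
    return out.dropna(subset=["value"]).reset_index(drop=True)


# --------------------------------------------------------------------------
# Binned target-proportion series
# --------------------------------------------------------------------------

@dataclass
class BinnedSeries:
    """Target-looking proportions on a uniform onset-locked 50 ms grid.

    ``values`` is an (n_series, n_bins) array of proportions in [0, 1] with
    NaN where a series had no AOI looking in a bin; ``transformed`` is the
    element-wise arcsine-square-root; ``index`` identifies each row.
    """

    bin_starts_ms: np.ndarray        # relative to word onset
    values: np.ndarray
    index: pd.DataFrame

    @property
    def transformed(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.arcsin(np.sqrt(self.values))


def binned_target_proportion(trials: pd.DataFrame, gaze: pd.DataFrame,
                             windows: AnalysisWindows | None = None,
                             layout: AOILayout | None = None) -> BinnedSeries:
    """Per-trial binned proportions over the cluster window.

    Bins are half-open 50 ms intervals locked to word onset, spanning
    [-cluster_pre_ms, end - onset).  Sample coverage intervals are split
    across bin boundaries so the accounting stays time-weighted.
    """
    windows = windows or AnalysisWindows()
    layout = layout or AOILayout()
    tr = trials.reset_index(drop=True)
    onset = tr["word_onset_ms"].to_numpy(float)
    rel_end = (tr["end_ms"].to_numpy(float) - onset).max()
    w0_rel = -windows.cluster_pre_ms
    n_bins = int(np.ceil((rel_end - w0_rel) / windows.bin_ms))
    bin_starts = w0_rel + windows.bin_ms * np.arange(n_bins)

    tgt = np.zeros((len(tr), n_bins))
    dis = np.zeros((len(tr), n_bins))
    if len(gaze):
        from .io import _sample_intervals, assign_aoi
        g = gaze.merge(tr[["trial_id", "target_side", "word_onset_ms",
                           "end_ms"]], on="trial_id", how="inner")
        from .io import _ensure_trialwise_sorted
        g = _ensure_trialwise_sorted(g)
        if len(g):
            a = g["t_ms"].to_numpy(float)
            b = _sample_intervals(g[["trial_id", "t_ms"]])
            on = g["word_onset_ms"].to_numpy(float)
            b = np.minimum(b, g["end_ms"].to_numpy(float))
            rel_a, rel_b = a - on, b - on
            label = np.atleast_1d(assign_aoi(g["x_px"], g["y_px"], g["valid"],
                                             g["target_side"], layout))
            row = pd.Categorical(g["trial_id"],
                                 categories=tr["trial_id"]).codes
            k0 = np.floor((rel_a - w0_rel) / windows.bin_ms).astype(int)
            kmax = np.floor((np.nextafter(rel_b, -np.inf) - w0_rel)
                            / windows.bin_ms).astype(int)
            span = int(max(0, (kmax - k0).max())) if len(k0) else 0
            for j in range(span + 1):
                k = k0 + j
                sel = (k <= kmax) & (k >= 0) & (k < n_bins)
                lo = np.maximum(rel_a, w0_rel + k * windows.bin_ms)
                hi = np.minimum(rel_b, w0_rel + (k + 1) * windows.bin_ms)
                dur = np.clip(hi - lo, 0.0, None)
                for arr, name in ((tgt, "target"), (dis, "distractor")):
                    m = sel & (label == name)
                    np.add.at(arr, (row[m], k[m]), dur[m])
    den = tgt + dis
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(den > 0, tgt / den, np.nan)
    # bins beyond a trial's own end stay missing
    over = bin_starts[None, :] >= (tr["end_ms"].to_numpy(float)
                                   - onset)[:, None]
    values[over] = np.nan
    return BinnedSeries(bin_starts_ms=bin_starts, values=values,
                        index=tr[["participant_id", "trial_id", "condition",
                                  "trial_type", "pair_id"]].copy())


def participant_series(series: BinnedSeries, condition=None,
                       trial_type=None) -> BinnedSeries:
    """Average trial series within participants for one analysis cell.

    Missing bins are skipped in the average (never treated as zero, which
    would bias toward the distractor); a participant bin with no
    contributing trial stays missing.
    """
    idx = series.index
    mask = np.ones(len(idx), dtype=bool)
    if condition is not None:
        mask &= (idx["condition"] == condition).to_numpy()
    if trial_type is not None:
        mask &= (idx["trial_type"] == trial_type).to_numpy()
    sub = series.values[mask]
    pids = idx.loc[mask, "participant_id"].to_numpy()
    uniq, codes = np.unique(pids, return_inverse=True)
    sums = np.zeros((len(uniq), sub.shape[1]))
    cnts = np.zeros((len(uniq), sub.shape[1]))
    ok = ~np.isnan(sub)
    np.add.at(sums, codes, np.where(ok, sub, 0.0))
    np.add.at(cnts, codes, ok.astype(float))
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(cnts > 0, sums / cnts, np.nan)
    return BinnedSeries(bin_starts_ms=series.bin_starts_ms, values=means,
                        index=pd.DataFrame({"participant_id": uniq}))
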