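"""Cluster-based permutation test on binned, transformed looking proportions.

Per 50 ms bin, a t statistic is computed across participants -- one-sample
against the transformed chance level arcsin(sqrt(0.5)) = pi/4 for the
vs-chance comparisons, or paired matching-vs-related.  Bins with |t| above
the threshold (default 2) are grouped into maximal contiguous runs of common
sign; a cluster's mass is the sum of its t values.  Family-wise p values
come from a permutation null of the maximum |mass| per permutation:
participant-level sign flips about chance for the one-sample comparisons,
participant-level condition-label swaps (equivalently sign flips of the
paired differences) for matching-vs-related.  The add-one estimator
p = (1 + #{null >= observed}) / (1 + n_permutations) keeps p strictly
positive.  A missing bin breaks contiguity (conservative).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .metrics import BinnedSeries, participant_series


@dataclass(frozen=True)
class ClusterConfig:
    t_threshold: float = 2.0
    n_permutations: int = 1000
    alpha: float = 0.05
    comparison: str = "matching_vs_chance"
    chance_level: float = 0.5      # transformed before differencing
    min_participants: int = 2
    two_sided_mass: bool = True    # compare |mass| to the max-|mass| null
    exhaustive: bool = False       # enumerate all 2^n sign patterns
    seed: int = 0

    def __post_init__(self):
        if self.n_permutations < 1:
            raise ValueError("need at least one permutation")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.comparison not in ("matching_vs_chance", "related_vs_chance",
                                   "matching_vs_related"):
            raise ValueError(f"unknown comparison {self.comparison!r}")


@dataclass
class Cluster:
    start_ms: float
    end_ms: float
    bin_slice: tuple
    mass: float
    p: float | None = None


@dataclass
class ClusterResult:
    comparison: str
    bin_starts_ms: np.ndarray
    t_values: np.ndarray
    clusters: list
    null_max_mass: np.ndarray
    n_participants: int
    config: ClusterConfig

    @property
    def significant(self) -> list:
        return [c for c in self.clusters if c.p is not None
                and c.p <= self.config.alpha]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "comparison": self.comparison, "start_ms": c.start_ms,
            "end_ms": c.end_ms, "mass": c.mass, "p": c.p}
            for c in self.clusters])


# --------------------------------------------------------------------------
# Building blocks
# --------------------------------------------------------------------------

def _comparison_matrix(series_by_cell: dict, config: ClusterConfig):
    """(participant x bin) matrix of deviations whose mean is tested vs 0.

    For vs-chance comparisons: transformed participant series minus the
    transformed chance level.  For matching-vs-related: the within-
    participant difference of transformed series (participants present in
    both cells).
    """
    if config.comparison in ("matching_vs_chance", "related_vs_chance"):
        cell = config.comparison.split("_vs_")[0]
        s = series_by_cell[cell]
        chance = float(np.arcsin(np.sqrt(config.chance_level)))
        return s.transformed - chance, s.bin_starts_ms
    sm, sr = series_by_cell["matching"], series_by_cell["related"]
    dm = pd.DataFrame(sm.transformed,
                      index=sm.index["participant_id"].to_numpy())
    dr = pd.DataFrame(sr.transformed,
                      index=sr.index["participant_id"].to_numpy())
    common = dm.index.intersection(dr.index)
    return (dm.loc[common].to_numpy() - dr.loc[common].to_numpy(),
            sm.bin_starts_ms)


def bin_tstats(dev: np.ndarray, min_participants: int = 2) -> np.ndarray:
    """Per-bin one-sample t of the deviation matrix against zero.

    NaN where fewer than ``min_participants`` non-missing values or where
    the bin has zero variance with zero mean undefined (returns NaN for
    sd == 0).
    """
    dev = np.asarray(dev, dtype=float)
    ok = ~np.isnan(dev)
    n = ok.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.nansum(np.where(ok, dev, 0.0), axis=0) / n
        ss = np.nansum(np.where(ok, (dev - mean) ** 2, 0.0), axis=0)
        sd = np.sqrt(ss / np.maximum(n - 1, 1))
        t = mean / (sd / np.sqrt(n))
    t[(sd == 0) & (mean == 0)] = 0.0  # all exactly at chance
    t[n < max(min_participants, 2)] = np.nan
    t[np.isinf(t)] = np.nan
    return t


def form_clusters(t: np.ndarray, threshold: float,
                  bin_starts_ms: np.ndarray | None = None,
                  bin_ms: float = 50.0) -> list:
    """Maximal contiguous same-sign runs with |t| > threshold.

    A missing (NaN) bin, a sub-threshold bin, or a sign change terminates a
    run.  Cluster mass is the sum of t values in the run.
    """
    t = np.asarray(t, dtype=float)
    if bin_starts_ms is None:
        bin_starts_ms = bin_ms * np.arange(len(t))
    clusters = []
    start, sign = None, 0
    for i, ti in enumerate(list(t) + [np.nan]):  # sentinel flushes the run
        s = 0 if (np.isnan(ti) or abs(ti) <= threshold) else int(np.sign(ti))
        if s != sign or s == 0:
            if sign != 0:
                clusters.append(Cluster(
                    start_ms=float(bin_starts_ms[start]),
                    end_ms=float(bin_starts_ms[i - 1] + bin_ms),
                    bin_slice=(start, i),
                    mass=float(np.sum(t[start:i]))))
            start, sign = (i, s) if s != 0 else (None, 0)
    return clusters


def max_cluster_mass(t: np.ndarray, threshold: float,
                     two_sided: bool = True) -> float:
    clusters = form_clusters(t, threshold)
    if not clusters:
        return 0.0
    masses = np.array([c.mass for c in clusters])
    return float(np.abs(masses).max() if two_sided else masses.max())


def permutation_null(dev: np.ndarray, config: ClusterConfig) -> np.ndarray:
    """Null distribution of the maximum cluster mass under sign flips.

    Each permutation flips the sign of whole participant series (about the
    chance level for vs-chance, equivalent to swapping condition labels for
    the paired comparison) and records the maximum |mass| across the window.
    With ``exhaustive=True`` all 2^n sign patterns are enumerated instead of
    sampled.
    """
    dev = np.asarray(dev, dtype=float)
    n = dev.shape[0]
    if n < 2:
        raise ValueError("need at least two participants to permute")
    if config.exhaustive:
        signs = np.array(list(product((1.0, -1.0), repeat=n)))
    else:
        rng = np.random.default_rng(config.seed)
        signs = rng.choice((1.0, -1.0), size=(config.n_permutations, n))
    out = np.empty(len(signs))
    for k, s in enumerate(signs):
        t = bin_tstats(dev * s[:, None], config.min_participants)
        out[k] = max_cluster_mass(t, config.t_threshold,
                                  config.two_sided_mass)
    return out


def cluster_pvalues(observed_t: np.ndarray, null: np.ndarray,
                    config: ClusterConfig, bin_starts_ms: np.ndarray,
                    n_participants: int) -> ClusterResult:
    """Attach permutation p values to the observed clusters.

    Monte-Carlo: p = (1 + #{null >= m}) / (1 + n_draws), never exactly 0.
    Exhaustive enumeration includes the identity permutation, so
    p = #{null >= m} / 2^n is already bounded away from 0.
    """
    bin_ms = float(np.median(np.diff(bin_starts_ms))) \
        if len(bin_starts_ms) > 1 else 50.0
    clusters = form_clusters(observed_t, config.t_threshold, bin_starts_ms,
                             bin_ms)
    for c in clusters:
        m = abs(c.mass) if config.two_sided_mass else c.mass
        ge = int((null >= m - 1e-12).sum())
        if config.exhaustive:
            c.p = ge / len(null)
        else:
            c.p = (1 + ge) / (1 + len(null))
    return ClusterResult(comparison=config.comparison,
                         bin_starts_ms=bin_starts_ms, t_values=observed_t,
                         clusters=clusters, null_max_mass=null,
                         n_participants=n_participants, config=config)


# --------------------------------------------------------------------------
# Front door
# --------------------------------------------------------------------------

def run_cluster_analysis(trial_series: BinnedSeries, condition: str,
                         config: ClusterConfig) -> ClusterResult:
    """Full cluster permutation analysis for one condition and comparison.

    ``trial_series`` is the per-trial binned output of
    :func:`iplgaze.metrics.binned_target_proportion`; participant-level
    series are averaged here per analysis cell.
    """
    cells = {}
    for ttype in ("matching", "related"):
        cells[ttype] = participant_series(trial_series, condition=condition,
                                          trial_type=ttype)
    dev, bins = _comparison_matrix(cells, config)
    dev = dev[~np.isnan(dev).all(axis=1)]
    if dev.shape[0] < 2:
        raise ValueError("fewer than two participants with data")
    t_obs = bin_tstats(dev, config.min_participants)
    null = permutation_null(dev, config)
    return cluster_pvalues(t_obs, null, config, bins, dev.shape[0])
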