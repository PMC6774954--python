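"""Self-validation experiments: calibration and effect recovery.

These drivers run the full analysis chain (simulate -> screen -> score ->
test) over many replicate synthetic cohorts to measure operating
characteristics of the pipeline itself: type-I error of the vs-chance
signed-rank test and of the cluster permutation test under null cohorts,
detection rate for a planted matching-trial effect of a prescribed
standardised size, and confidence-interval coverage for a planted linear
age slope in the mixed model.  They are what the test suite and the
reproduction script call; replicate counts are arguments so desk-scale runs
stay cheap.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .cluster import ClusterConfig, run_cluster_analysis
from .cohort import CohortConfig, EffectSpec, Missingness, simulate_cohort
from .inference import fit_age_model, wilcoxon_one_sample
from .metrics import aggregate_scores, binned_target_proportion, pair_scores
from .screening import screen_trials

MATCHING_ONLY = {"matching": 8, "related": 0, "control": 0}


def _subject_matching_means(data):
    """By-subject mean matching pair score after full screening."""
    report = screen_trials(data.trials, data.gaze, data.questionnaires)
    scores = pair_scores(report.included_trials(), data.gaze)
    if not len(scores):
        return np.array([])
    subj = aggregate_scores(scores[scores["trial_type"] == "matching"],
                            by="subject", within=())
    return subj["score"].to_numpy()


def null_calibration(n_replicates: int = 500, n_infants: int = 20,
                     n_permutations: int = 250, alpha: float = 0.05,
                     seed: int = 0) -> dict:
    """Type-I error of the battery under all-null cohorts.

    Each replicate simulates a cohort with every injected preference zero,
    runs screening and scoring, then (a) the one-tailed vs-chance
    signed-rank test on by-subject matching scores and (b) the cluster
    permutation test of matching trials against chance (conditions pooled).
    Returns the two rejection rates with their binomial standard errors.
    """
    rng = np.random.default_rng(seed)
    wil_rej = clu_rej = n_ok = 0
    for rep in range(n_replicates):
        cfg = CohortConfig(n_infants=n_infants,
                           effect_spec=EffectSpec.null(),
                           seed=int(rng.integers(2 ** 31)))
        data = simulate_cohort(cfg)
        report = screen_trials(data.trials, data.gaze, data.questionnaires)
        included = report.included_trials()
        scores = pair_scores(included, data.gaze)
        subj = aggregate_scores(scores[scores["trial_type"] == "matching"],
                                by="subject", within=())
        if len(subj) < 2:
            continue
        n_ok += 1
        rep_w = wilcoxon_one_sample(subj["score"].to_numpy(), 0.0,
                                    tail="greater")
        wil_rej += rep_w.p <= alpha

        series = binned_target_proportion(
            included[included["trial_type"] == "matching"], data.gaze)
        ccfg = ClusterConfig(n_permutations=n_permutations, alpha=alpha,
                             comparison="matching_vs_chance",
                             seed=int(rng.integers(2 ** 31)))
        res = run_cluster_analysis(series, None, ccfg)
        clu_rej += bool(res.significant)
    return {
        "n_replicates": n_ok, "alpha": alpha,
        "wilcoxon_rejection_rate": wil_rej / n_ok,
        "cluster_familywise_rate": clu_rej / n_ok,
        "binomial_se": float(np.sqrt(alpha * (1 - alpha) / n_ok)),
    }


def calibrate_delta_for_d(target_d: float, pilot_infants: int = 200,
                          seed: int = 0,
                          missingness: Missingness | None = None) -> float:
    """Preference shift delta whose by-subject score effect size is target_d.

    The by-subject mean matching score has expectation 2*delta, so delta =
    target_d * sd / 2 with sd estimated from one large null pilot cohort
    under the same conditions.
    """
    missingness = missingness or Missingness(0.0, 0.05, 0.0)
    cfg = CohortConfig(n_infants=pilot_infants, seed=seed,
                       effect_spec=EffectSpec.null(),
                       trial_layout=dict(MATCHING_ONLY),
                       missingness=missingness)
    means = _subject_matching_means(simulate_cohort(cfg))
    sd = float(np.std(means, ddof=1))
    return target_d * sd / 2.0


def effect_detection(n_replicates: int = 500, n_infants: int = 23,
                     target_d: float = 0.44, alpha: float = 0.05,
                     seed: int = 0) -> dict:
    """Detection rate of a planted matching effect of standardised size d.

    Mirrors the older-age-group configuration: n infants analysed with a
    one-tailed vs-chance signed-rank test on by-subject matching scores.
    The injected preference shift is calibrated from a null pilot so the
    population effect size is ``target_d``; missingness is disabled so the
    analysed sample size stays fixed.
    """
    from .inference import power_one_sample_t

    missingness = Missingness(0.0, 0.05, 0.0)
    delta = calibrate_delta_for_d(target_d, seed=seed + 1,
                                  missingness=missingness)
    eff = EffectSpec.null()
    eff = dataclasses.replace(eff, delta={
        ("context", "matching"): delta, ("frequency", "matching"): delta,
        ("context", "related"): 0.0, ("frequency", "related"): 0.0})
    rng = np.random.default_rng(seed)
    hits = n_ok = 0
    for rep in range(n_replicates):
        cfg = CohortConfig(n_infants=n_infants, effect_spec=eff,
                           trial_layout=dict(MATCHING_ONLY),
                           missingness=missingness,
                           seed=int(rng.integers(2 ** 31)))
        means = _subject_matching_means(simulate_cohort(cfg))
        if len(means) < 2:
            continue
        n_ok += 1
        hits += wilcoxon_one_sample(means, 0.0, tail="greater").p <= alpha
    return {
        "n_replicates": n_ok, "delta": delta, "target_d": target_d,
        "detection_rate": hits / n_ok,
        "analytic_t_power": power_one_sample_t(target_d, n_infants, alpha,
                                               "greater"),
    }


def age_slope_recovery(n_replicates: int = 150, n_infants: int = 30,
                       slope_per_day: float = 0.003,
                       seed: int = 0) -> dict:
    """Coverage of the mixed model's 95% CI for a planted age slope.

    The generator applies the slope to matching-trial preference delta
    (score slope 2*slope per day); on the log(score + 2) response the
    implied slope is approximately (2*slope)/2 = slope per day, the target
    the matching-trials simple-effect CI should cover.
    """
    eff = EffectSpec(
        delta={("context", "matching"): 0.04,
               ("frequency", "matching"): 0.04,
               ("context", "related"): 0.0, ("frequency", "related"): 0.0},
        age_slope_per_day={("context", "matching"): slope_per_day,
                           ("frequency", "matching"): slope_per_day,
                           ("context", "related"): 0.0,
                           ("frequency", "related"): 0.0})
    target = slope_per_day  # log-scale (see docstring)
    rng = np.random.default_rng(seed)
    covered = n_ok = 0
    for rep in range(n_replicates):
        cfg = CohortConfig(n_infants=n_infants, effect_spec=eff,
                           missingness=Missingness(0.05, 0.05, 1e-5),
                           seed=int(rng.integers(2 ** 31)))
        data = simulate_cohort(cfg)
        report = screen_trials(data.trials, data.gaze, data.questionnaires)
        scores = pair_scores(report.included_trials(), data.gaze)
        if scores["participant_id"].nunique() < 3:
            continue
        from .io import participant_ages
        ages = participant_ages(data.questionnaires)
        model = fit_age_model(scores, ages,
                              include_trial_age_interaction=True)
        simple = model.simple_effects
        row = simple[simple["trial_type"] == "matching"]
        if not len(row):
            continue
        n_ok += 1
        covered += bool(row["ci_low"].iloc[0] <= target
                        <= row["ci_high"].iloc[0])
    return {"n_replicates": n_ok, "slope_per_day": slope_per_day,
            "target_log_slope": target, "coverage": covered / n_ok}
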