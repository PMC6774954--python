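"""End-to-end orchestration: configuration, stages, artifacts, figures.

A run is described by a :class:`RunConfig` -- either paths to the three
input tables or a ``simulate`` block with a :class:`~iplgaze.cohort.CohortConfig`.
``run_pipeline`` executes screening -> scores -> cluster permutation ->
inference battery, writes tidy CSV/JSON artifacts plus a log into the
output directory, and stamps every artifact manifest with a hash of the
resolved configuration.  Runs are deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as _cohort
from . import io as _io
from .cluster import ClusterConfig, run_cluster_analysis
from .inference import (comprehension_split_analysis, fit_age_model,
                        freq_imbalance_correlation, median_split_battery,
                        min_frequency_ratio, power_one_sample_t,
                        wilcoxon_one_sample)
from .metrics import (aggregate_scores, baseline_corrected,
                      binned_target_proportion, pair_scores)
from .screening import ExclusionConfig, control_quality, screen_trials

log = logging.getLogger("iplgaze")


@dataclass
class RunConfig:
    """Serializable description of a full analysis run."""

    gaze_path: str | None = None
    trials_path: str | None = None
    questionnaires_path: str | None = None
    simulate: _cohort.CohortConfig | None = None
    windows: _io.AnalysisWindows = field(default_factory=_io.AnalysisWindows)
    layout: _io.AOILayout = field(default_factory=_io.AOILayout)
    exclusion: ExclusionConfig = field(default_factory=ExclusionConfig)
    cluster_permutations: int = 1000
    cluster_t_threshold: float = 2.0
    cluster_alpha: float = 0.05
    control_null: float = 0.0
    vs_chance_tail: str = "greater"
    median_split_days: int = 230
    seed: int = 0
    outdir: str = "iplgaze_out"
    figures: bool = False

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("delta", "age_slope_per_day"):
            sim = d.get("simulate")
            if sim:
                sim["effect_spec"][key] = {
                    f"{c}/{t}": v
                    for (c, t), v in sim["effect_spec"][key].items()}
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.resolved(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        for key, typ in (("windows", _io.AnalysisWindows),
                         ("layout", _io.AOILayout),
                         ("exclusion", ExclusionConfig)):
            if isinstance(raw.get(key), dict):
                raw[key] = typ(**{k: tuple(v) if isinstance(v, list) else v
                                  for k, v in raw[key].items()})
        cfg = cls(**{k: v for k, v in raw.items()
                     if k in {f.name for f in dataclasses.fields(cls)}})
        if sim is not None:
            eff = sim.pop("effect_spec", None)
            kwargs = dict(sim)
            if eff is not None:
                for key in ("delta", "age_slope_per_day"):
                    if key in eff:
                        eff[key] = {tuple(k.split("/")): v
                                    for k, v in eff[key].items()}
                kwargs["effect_spec"] = _cohort.EffectSpec(**eff)
            if "missingness" in kwargs:
                kwargs["missingness"] = _cohort.Missingness(
                    **kwargs["missingness"])
            cfg.simulate = _cohort.CohortConfig(**kwargs)
        return cfg


def _write_csv(df: pd.DataFrame, path: Path):
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns a manifest of artifact paths + results.

    Any stage failure aborts with the stage name in the exception message.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    manifest = {"config_hash": config.config_hash(),
                "config": config.resolved(), "artifacts": {}, "results": {}}
    try:
        stage = "simulate"
        if config.simulate is not None:
            sim_cfg = dataclasses.replace(config.simulate, seed=config.seed)
            data = _cohort.simulate_cohort(sim_cfg, layout=config.layout)
            paths = data.write(out / "inputs")
            config.gaze_path = paths["gaze"]
            config.trials_path = paths["trials"]
            config.questionnaires_path = paths["questionnaires"]
            log.info("simulated cohort of %d infants (seed %d)",
                     sim_cfg.n_infants, config.seed)

        stage = "read"
        gaze = _io.read_gaze_table(config.gaze_path)
        trials = _io.read_trial_sheet(config.trials_path)
        quest = _io.read_questionnaires(config.questionnaires_path)
        ages = _io.participant_ages(quest)
        stimuli = _io.load_packaged_stimuli()

        stage = "screening"
        report = screen_trials(trials, gaze, quest, config.exclusion,
                               config.windows, config.layout)
        _write_csv(report.trials, out / "screening_trials.csv")
        _write_csv(report.participants, out / "screening_participants.csv")
        (out / "screening_summary.txt").write_text(report.summary() + "\n")
        for reason, cnt in sorted(report.reason_counts.items()):
            log.info("excluded %d trials: %s", cnt, reason)
        included = report.included_trials()
        manifest["results"]["n_retained"] = len(
            report.retained_participants())

        stage = "control_quality"
        if (trials["trial_type"] == "control").any():
            cq = control_quality(trials, gaze, null_value=config.control_null,
                                 windows=config.windows,
                                 layout=config.layout)
            manifest["results"]["control"] = {
                "mean_fixation_s": cq.mean_fixation_s,
                "mean_proportion_of_trial": cq.mean_proportion_of_trial,
                "test": cq.test.as_dict()}

        stage = "scores"
        scores = pair_scores(included, gaze, config.windows, config.layout)
        _write_csv(scores, out / "pair_scores.csv")
        subj = aggregate_scores(scores, by="subject")
        item = aggregate_scores(scores, by="item")
        _write_csv(subj, out / "subject_scores.csv")
        _write_csv(item, out / "item_scores.csv")

        stage = "paired_tests"
        battery = []
        pooled = aggregate_scores(scores, by="subject",
                                  within=("trial_type",))
        for frame, grouping, keys in ((subj, "subject",
                                       ["condition", "trial_type"]),
                                      (item, "item",
                                       ["condition", "trial_type"]),
                                      (pooled, "subject", ["trial_type"])):
            for key, grp in frame.groupby(keys):
                key = key if isinstance(key, tuple) else (key,)
                if len(grp) < 2:
                    continue
                rep = wilcoxon_one_sample(grp["score"].to_numpy(), mu0=0.0,
                                          tail=config.vs_chance_tail)
                rep.grouping = grouping
                battery.append({**dict(zip(keys, key)),
                                "pooled": len(key) == 1, **rep.as_dict()})
        battery = pd.DataFrame(battery)
        _write_csv(battery, out / "paired_tests.csv")

        stage = "cluster"
        series = binned_target_proportion(included, gaze, config.windows,
                                          config.layout)
        cluster_rows, tvalue_rows = [], []
        for ci, cond in enumerate(("context", "frequency")):
            for mi, comparison in enumerate(("matching_vs_chance",
                                             "related_vs_chance",
                                             "matching_vs_related")):
                ttypes = set(included.loc[included["condition"] == cond,
                                          "trial_type"])
                need = ({"matching", "related"}
                        if comparison == "matching_vs_related"
                        else {comparison.split("_vs_")[0]})
                if not need <= ttypes:
                    continue
                ccfg = ClusterConfig(
                    t_threshold=config.cluster_t_threshold,
                    n_permutations=config.cluster_permutations,
                    alpha=config.cluster_alpha, comparison=comparison,
                    seed=config.seed + 101 * ci + 11 * mi)
                res = run_cluster_analysis(series, cond, ccfg)
                df = res.to_frame()
                df.insert(0, "condition", cond)
                cluster_rows.append(df)
                tvalue_rows.append(pd.DataFrame({
                    "condition": cond, "comparison": comparison,
                    "bin_start_ms": res.bin_starts_ms, "t": res.t_values}))
        clusters = (pd.concat(cluster_rows, ignore_index=True)
                    if cluster_rows else pd.DataFrame())
        _write_csv(clusters, out / "clusters.csv")
        _write_csv(pd.concat(tvalue_rows, ignore_index=True)
                   if tvalue_rows else pd.DataFrame(), out / "bin_tstats.csv")

        stage = "inference"
        extra = {}
        if len(scores) and scores["trial_type"].nunique() == 2:
            model = fit_age_model(scores, ages,
                                  include_trial_age_interaction=True)
            _write_csv(model.terms, out / "age_model_terms.csv")
            _write_csv(model.simple_effects, out / "age_model_simple.csv")
            extra["age_model_converged"] = model.converged
        split = median_split_battery(subj, ages,
                                     split_days=config.median_split_days,
                                     tail=config.vs_chance_tail)
        _write_csv(split, out / "median_split.csv")
        match_item = item[item["trial_type"] == "matching"].groupby(
            "pair_id", as_index=False).agg(score=("score", "mean"))
        if len(match_item) >= 3:
            corr = freq_imbalance_correlation(match_item, stimuli)
            extra["freq_imbalance"] = {k: corr[k]
                                       for k in ("r", "p", "bf10", "n")}
        base = baseline_corrected(
            included[included["trial_type"] == "matching"], gaze,
            config.windows, config.layout)
        _write_csv(base[["participant_id", "trial_id", "condition",
                         "pair_id", "target_word", "value"]],
                   out / "baseline_corrected.csv")
        if len(base):
            comp = comprehension_split_analysis(base, quest)
            _write_csv(comp["cells"], out / "comprehension_cells.csv")
            extra["comprehension_note"] = comp["note"]
        extra["design"] = {
            "power_d041_n50": power_one_sample_t(0.41, 50, 0.05, "two-sided"),
            "min_frequency_ratio": min_frequency_ratio(stimuli)}
        manifest["results"].update(extra)

        if config.figures:
            stage = "figures"
            figs = make_figures(subj, series, out)
            manifest["artifacts"]["figures"] = figs

        stage = "manifest"
        manifest["artifacts"].update({p.name: str(p) for p in out.glob("*.csv")})
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True, default=str))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
    return manifest


# --------------------------------------------------------------------------
# Figures
# --------------------------------------------------------------------------

def make_figures(subject_scores: pd.DataFrame, series, outdir) -> list:
    """Boxplots of difference scores and the binned time-course plot."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .metrics import participant_series

    outdir = Path(outdir)
    made = []
    if len(subject_scores):
        fig, ax = plt.subplots(figsize=(6, 4))
        cells, labels = [], []
        for (cond, ttype), grp in subject_scores.groupby(
                ["condition", "trial_type"]):
            cells.append(grp["score"].to_numpy())
            labels.append(f"{cond}\n{ttype}")
        ax.boxplot(cells, tick_labels=labels)
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_ylabel("difference in looking proportion")
        fig.tight_layout()
        p = outdir / "difference_scores.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        made.append(str(p))

    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, cond in zip(axes, ("context", "frequency")):
        for ttype, color in (("matching", "tab:red"), ("related",
                                                       "tab:blue")):
            ps = participant_series(series, condition=cond, trial_type=ttype)
            if not len(ps.values):
                continue
            m = np.nanmean(ps.values, axis=0)
            n = (~np.isnan(ps.values)).sum(axis=0)
            se = np.nanstd(ps.values, axis=0, ddof=1) / np.sqrt(
                np.maximum(n, 1))
            x = ps.bin_starts_ms
            ax.plot(x, m, color=color, label=ttype)
            ax.fill_between(x, m - se, m + se, color=color, alpha=0.2)
        ax.axvline(0, color="red", lw=0.8)
        ax.axvline(367, color="grey", lw=0.8)
        ax.axhline(0.5, color="grey", lw=0.5, ls=":")
        ax.set_title(cond)
        ax.set_xlabel("time from word onset (ms)")
    axes[0].set_ylabel("proportion target looking")
    axes[0].legend()
    fig.tight_layout()
    p = outdir / "timecourse.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    made.append(str(p))
    return made
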