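"""Statistical battery: signed-rank tests, JZS Bayes factors, mixed-effects
age models, median-split analyses, frequency-imbalance correlation and
design-stage computations (power, stimulus frequency-ratio floor).

Conventions
-----------
* The Wilcoxon signed-rank statistic is the R-style V: the sum of the ranks
  of the positive differences after dropping exact ties with the null value
  (so V_max = n(n+1)/2 when every value exceeds mu0).  p values are exact
  for n <= 25 without ties, otherwise a normal approximation with
  continuity correction.
* Bayes factors for location tests are one-sample Jeffreys-Zellner-Siow
  BF10 with a Cauchy(0, sqrt(2)/2) effect-size prior, computed by
  numerical integration; they are reported alongside the signed-rank V,
  i.e. the BF is computed from the same values via the t-based JZS form.
* Confidence intervals are two-sided t-based intervals on the mean
  (a bootstrap percentile interval is available via ``ci="bootstrap"``).
* Mixed models are fit with statsmodels MixedLM using crossed random
  intercepts (infant and word pair) as variance components; reported
  F values for single-df fixed effects are squared Wald z statistics with a
  normal reference -- an approximation to the Satterthwaite-style F tests
  of dedicated mixed-model software.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, stats

DEFAULT_BF_SCALE = float(np.sqrt(2) / 2)


@dataclass
class StatReport:
    """One test's report in the style n / mean / CI / statistic / p / d / BF."""

    n: int
    mean: float
    ci_low: float
    ci_high: float
    statistic: float
    statistic_name: str
    p: float
    cohens_d: float
    bf10: float | None
    tail: str
    grouping: str = "subject"
    note: str = ""

    def __post_init__(self):
        if self.ci_low > self.ci_high:
            raise ValueError("CI bounds out of order")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p outside [0, 1]")
        if self.bf10 is not None and self.bf10 <= 0:
            raise ValueError("BF10 must be positive")

    def as_dict(self) -> dict:
        return {"n": self.n, "mean": self.mean, "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "statistic": self.statistic, "stat": self.statistic_name,
                "p": self.p, "cohens_d": self.cohens_d, "bf10": self.bf10,
                "tail": self.tail, "grouping": self.grouping,
                "note": self.note}


# --------------------------------------------------------------------------
# Signed-rank test
# --------------------------------------------------------------------------

def signed_rank_v(values, mu0: float = 0.0) -> float:
    """R-style V: sum of ranks of positive differences (zeros dropped)."""
    d = np.asarray(values, dtype=float) - mu0
    d = d[d != 0]
    if not len(d):
        return 0.0
    ranks = stats.rankdata(np.abs(d))
    return float(ranks[d > 0].sum())


def wilcoxon_one_sample(values, mu0: float = 0.0, tail: str = "greater",
                        ci: str = "t", ci_level: float = 0.95,
                        bf_scale: float = DEFAULT_BF_SCALE,
                        rng=None) -> StatReport:
    """One-sample Wilcoxon signed-rank test against ``mu0``.

    ``tail`` is 'greater' (values exceed mu0), 'less', or 'two-sided'.
    Returns the full report: V, p, mean with CI, Cohen's d = (mean - mu0)/sd
    and the JZS BF10 on the same values.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 1:
        raise ValueError("empty sample")
    d = x - mu0
    nz = d[d != 0]
    v = signed_rank_v(x, mu0)
    note = ""
    if len(nz) == 0:
        p = 1.0
        note = "degenerate: all values equal mu0"
    else:
        ties = len(np.unique(np.abs(nz))) < len(nz)
        method = "exact" if (len(nz) <= 25 and not ties) else "approx"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.wilcoxon(nz, alternative=tail, method=method,
                                 correction=(method == "approx"))
        p = float(res.pvalue)
        if method == "approx":
            note = "normal approximation"
    mean = float(x.mean())
    sd = float(x.std(ddof=1)) if len(x) > 1 else np.nan
    if len(x) > 1 and sd > 0:
        half = stats.t.ppf(0.5 + ci_level / 2, len(x) - 1) * sd / np.sqrt(len(x))
        if ci == "bootstrap":
            rng = rng if rng is not None else np.random.default_rng(0)
            boots = rng.choice(x, size=(2000, len(x)), replace=True).mean(axis=1)
            lo, hi = np.quantile(boots, [(1 - ci_level) / 2,
                                         0.5 + ci_level / 2])
        else:
            lo, hi = mean - half, mean + half
        cohen = (mean - mu0) / sd
        bf = jzs_bf_one_sample(x, mu0=mu0, scale=bf_scale)
    else:
        lo = hi = mean
        cohen = 0.0
        bf = None
    return StatReport(n=len(x), mean=mean, ci_low=float(lo), ci_high=float(hi),
                      statistic=v, statistic_name="V", p=p,
                      cohens_d=float(cohen), bf10=bf, tail=tail, note=note)


# --------------------------------------------------------------------------
# JZS Bayes factor
# --------------------------------------------------------------------------

def jzs_bf_one_sample(values=None, mu0: float = 0.0,
                      scale: float = DEFAULT_BF_SCALE, *,
                      t: float | None = None, n: int | None = None) -> float:
    """One-sample JZS Bayes factor BF10 with a Cauchy(0, scale) prior.

    Either raw ``values`` or the (t, n) pair may be supplied.  Computed by
    quadrature over the Zellner-Siow mixture: g is inverse-gamma(1/2,
    scale^2/2) distributed, and BF10 is the ratio of the marginal likelihood
    under the alternative to the central-t likelihood under the null.
    """
    if values is not None:
        x = np.asarray(values, dtype=float) - mu0
        n = len(x)
        if n < 2:
            raise ValueError("need n >= 2")
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValueError("zero variance")
        t = float(x.mean() / (sd / np.sqrt(n)))
    if t is None or n is None or n < 2:
        raise ValueError("supply values or both t and n")
    nu = n - 1
    r2 = scale * scale

    def integrand(g):
        # inverse-gamma(1/2, r^2/2) mixing density: r/sqrt(2*pi) g^-3/2 e^{-r^2/2g}
        return ((1 + n * g) ** -0.5
                * (1 + t * t / ((1 + n * g) * nu)) ** (-(nu + 1) / 2)
                * (r2 / (2 * np.pi)) ** 0.5
                * g ** -1.5 * np.exp(-r2 / (2 * g)))

    num, _ = integrate.quad(integrand, 0, np.inf, limit=200)
    den = (1 + t * t / nu) ** (-(nu + 1) / 2)
    return float(num / den)


# --------------------------------------------------------------------------
# Power and stimulus design
# --------------------------------------------------------------------------

def power_one_sample_t(d: float, n: int, alpha: float = 0.05,
                       tail: str = "two-sided") -> float:
    """Power of the one-sample t test via the noncentral t distribution."""
    if n < 2:
        raise ValueError("need n >= 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha outside (0, 1)")
    df = n - 1
    ncp = d * np.sqrt(n)
    if tail == "two-sided":
        tc = stats.t.ppf(1 - alpha / 2, df)
        return float(1 - stats.nct.cdf(tc, df, ncp)
                     + stats.nct.cdf(-tc, df, ncp))
    if tail in ("greater", "one-sided"):
        tc = stats.t.ppf(1 - alpha, df)
        return float(1 - stats.nct.cdf(tc, df, ncp))
    raise ValueError(f"unknown tail {tail!r}")


def min_frequency_ratio(stimulus_table: pd.DataFrame,
                        condition: str = "frequency",
                        role: str = "referent") -> float:
    """Smallest within-pair high/low CDS-frequency ratio (design floor 7).

    Computed over the referent pairs of the frequency condition; the design
    guarantees the frequent word of each pair is heard at least seven times
    more often than its partner.
    """
    sub = stimulus_table[(stimulus_table["condition"] == condition)
                         & (stimulus_table["role"] == role)]
    ratios = []
    for pair, grp in sub.groupby("pair_id"):
        f = np.sort(grp["frequency"].to_numpy(float))
        if len(f) != 2 or np.isnan(f).any():
            continue
        if f[0] <= 0:
            raise ValueError(f"pair {pair!r} has non-positive low frequency")
        ratios.append(f[1] / f[0])
    if not ratios:
        raise ValueError("no complete frequency pairs in table")
    return float(min(ratios))


# --------------------------------------------------------------------------
# Mixed-effects age model
# --------------------------------------------------------------------------

@dataclass
class MixedModelReport:
    terms: pd.DataFrame          # coef, se, z, F=z^2, p per fixed term
    simple_effects: pd.DataFrame
    converged: bool
    n_obs: int
    formula: str
    note: str = ""


def _fit_mixedlm(formula: str, data: pd.DataFrame, vc: dict):
    import statsmodels.regression.mixed_linear_model as mlm
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = mlm.MixedLM.from_formula(formula, data,
                                      groups=np.ones(len(data)),
                                      re_formula="0", vc_formula=vc)
        res = md.fit(reml=True)
        res.bse_fe  # force SE computation while warnings are suppressed
    return res


def _wald_table(res, skip=("Intercept",)) -> pd.DataFrame:
    rows = []
    fe = res.fe_params
    for name in fe.index:
        if name in skip or name.endswith("Var"):
            continue
        coef = float(fe[name])
        se = float(res.bse_fe[name])
        z = coef / se if se > 0 else np.nan
        rows.append({"term": name, "coef": coef, "se": se, "z": z,
                     "F": z * z, "p": 2 * stats.norm.sf(abs(z)),
                     "ci_low": coef - 1.96 * se, "ci_high": coef + 1.96 * se})
    return pd.DataFrame(rows)


def fit_age_model(scores: pd.DataFrame, ages: pd.Series,
                  include_trial_age_interaction: bool = False,
                  offset: float = 2.0) -> MixedModelReport:
    """Mixed-effects regression of log(score + offset) on the design factors.

    Fixed effects: trial type, condition, their interaction, and mean-
    centred age in days (optionally a trial-by-age interaction); random
    intercepts for infant and word pair.  ``scores`` is the tidy per-pair
    frame from :func:`iplgaze.metrics.pair_scores` (NOT averaged over
    pairs).  Simple effects report the age slope separately per trial type.
    """
    if scores["participant_id"].nunique() < 2 or \
            scores["pair_id"].nunique() < 2:
        raise ValueError("need at least two infants and two pairs")
    d = scores.merge(ages.rename("age_days"), left_on="participant_id",
                     right_index=True, how="left").copy()
    if (d["score"] + offset <= 0).any():
        raise ValueError("log argument not positive; increase offset")
    d["y"] = np.log(d["score"] + offset)
    d["age_c"] = d["age_days"] - d["age_days"].mean()
    vc = {"infant": "0 + C(participant_id)", "pair": "0 + C(pair_id)"}
    rhs = "C(trial_type) * C(condition) + age_c"
    if include_trial_age_interaction:
        rhs += " + C(trial_type):age_c"
    formula = f"y ~ {rhs}"
    res = _fit_mixedlm(formula, d, vc)
    terms = _wald_table(res)

    simple = []
    for ttype, grp in d.groupby("trial_type"):
        if grp["participant_id"].nunique() < 2:
            continue
        sub = _fit_mixedlm("y ~ age_c + C(condition)", grp, vc)
        coef = float(sub.fe_params["age_c"])
        se = float(sub.bse_fe["age_c"])
        z = coef / se if se > 0 else np.nan
        simple.append({"trial_type": ttype, "age_slope": coef, "se": se,
                       "z": z, "F": z * z, "p": 2 * stats.norm.sf(abs(z)),
                       "ci_low": coef - 1.96 * se,
                       "ci_high": coef + 1.96 * se,
                       "converged": bool(sub.converged)})
    note = "" if res.converged else \
        "variance components at or near boundary; Wald tests approximate"
    return MixedModelReport(terms=terms, simple_effects=pd.DataFrame(simple),
                            converged=bool(res.converged), n_obs=len(d),
                            formula=formula, note=note)


# --------------------------------------------------------------------------
# Median split battery
# --------------------------------------------------------------------------

def median_split_battery(subject_scores: pd.DataFrame, ages: pd.Series,
                         split_days: int = 230, mu0: float = 0.0,
                         tail: str = "greater",
                         by_condition: bool = True) -> pd.DataFrame:
    """Signed-rank tests per age group x trial type (x condition).

    The younger group is [min, split_days - 1]; an infant aged exactly
    ``split_days`` belongs to the older group.  Empty cells are skipped with
    a warning row (n = 0).
    """
    d = subject_scores.merge(ages.rename("age_days"),
                             left_on="participant_id", right_index=True,
                             how="left")
    d["age_group"] = np.where(d["age_days"] >= split_days, "older", "younger")
    keys = ["age_group", "trial_type"] + (["condition"] if by_condition
                                          else [])
    # when pooling conditions, average an infant's two condition cells first
    if not by_condition:
        d = d.groupby(["participant_id", "age_group", "trial_type"],
                      as_index=False).agg(score=("score", "mean"),
                                          age_days=("age_days", "first"))
    rows = []
    for key, grp in d.groupby(keys):
        key = key if isinstance(key, tuple) else (key,)
        vals = grp["score"].to_numpy()
        if len(vals) == 0:
            continue
        rep = wilcoxon_one_sample(vals, mu0=mu0, tail=tail)
        rows.append({**dict(zip(keys, key)), **rep.as_dict()})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Frequency-imbalance correlation
# --------------------------------------------------------------------------

def freq_imbalance_correlation(item_scores: pd.DataFrame,
                               stimulus_table: pd.DataFrame,
                               tail: str = "greater") -> dict:
    """Pearson correlation of per-pair effects with |frequency difference|.

    ``item_scores`` must have one row per pair_id with a ``score`` column
    (the by-item average difference in looking proportion).  The frequency
    imbalance of a pair is the absolute difference of its two referent
    words' CDS frequencies.  Returns r, one-sided p, BF10 (JZS correlation
    Bayes factor) and the paired table.
    """
    ref = stimulus_table[stimulus_table["role"] == "referent"]
    imb = ref.groupby("pair_id")["frequency"].agg(
        lambda f: float(abs(f.iloc[0] - f.iloc[1])))
    d = item_scores.set_index("pair_id")["score"].to_frame().join(
        imb.rename("freq_imbalance"), how="inner").dropna()
    if len(d) < 3:
        raise ValueError("need at least three pairs")
    r, p_two = stats.pearsonr(d["freq_imbalance"], d["score"])
    if tail == "greater":
        p = p_two / 2 if r >= 0 else 1 - p_two / 2
    elif tail == "less":
        p = p_two / 2 if r <= 0 else 1 - p_two / 2
    else:
        p = p_two
    import pingouin as pg
    bf = float(pg.bayesfactor_pearson(r, len(d)))
    return {"r": float(r), "p": float(p), "bf10": bf, "n": len(d),
            "tail": tail, "pairs": d.reset_index()}


# --------------------------------------------------------------------------
# CDI comprehension split
# --------------------------------------------------------------------------

def comprehension_split_analysis(baseline_scores: pd.DataFrame,
                                 questionnaires: pd.DataFrame,
                                 offset: float = 2.0,
                                 tail: str = "two-sided") -> dict:
    """Condition x comprehension mixed model on baseline-corrected looking.

    ``baseline_scores`` is the per-trial output of
    :func:`iplgaze.metrics.baseline_corrected` (matching trials); each
    trial's target word is joined with the parental CDI "understands" flag.
    Fits log(value + offset) ~ condition * comprehension with by-subject and
    by-item (pair) random intercepts, plus per-cell signed-rank tests.
    If every flag is identical the comprehension factor is dropped with a
    warning note.
    """
    cdi = questionnaires.set_index(["participant_id", "word"])[
        "cdi_understands"]
    d = baseline_scores.copy()
    key = pd.MultiIndex.from_frame(d[["participant_id", "target_word"]])
    d["understood"] = cdi.reindex(key).to_numpy()
    d = d.dropna(subset=["understood", "value"])
    d["understood"] = np.where(d["understood"].astype(float) > 0, "yes", "no")
    note_deg = ""
    degenerate = d["value"] + offset <= 0
    if degenerate.any():
        # value == -offset (all-distractor post after all-target pre) has no
        # finite log; such saturated trials are dropped, not clipped
        note_deg = f"dropped {int(degenerate.sum())} saturated trial(s)"
        d = d[~degenerate]
    d["y"] = np.log(d["value"] + offset)
    vc = {"infant": "0 + C(participant_id)", "pair": "0 + C(pair_id)"}
    note = note_deg
    if d["understood"].nunique() < 2:
        note = (note + "; " if note else "") + \
            "comprehension factor constant; dropped from the model"
        formula = "y ~ C(condition)"
    else:
        formula = "y ~ C(condition) * C(understood)"
    res = _fit_mixedlm(formula, d, vc)
    terms = _wald_table(res)
    cells = []
    for (cond, und), grp in d.groupby(["condition", "understood"]):
        per_subj = grp.groupby("participant_id")["value"].mean()
        if len(per_subj) < 2:
            continue
        rep = wilcoxon_one_sample(per_subj.to_numpy(), mu0=0.0, tail=tail)
        cells.append({"condition": cond, "understood": und,
                      **rep.as_dict()})
    return {"terms": terms, "cells": pd.DataFrame(cells),
            "converged": bool(res.converged), "note": note,
            "formula": formula, "n_obs": len(d)}


@dataclass(frozen=True)
class DesignParams:
    """Planning-stage constants of the study design."""

    effect_size_d: float = 0.41
    alpha: float = 0.05
    n_planned: int = 50
    median_split_days: int = 230
    frequency_ratio_floor: float = 7.0
    power_target: float = 0.80
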