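import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from iplgaze import (comprehension_split_analysis, fit_age_model,
                     freq_imbalance_correlation, jzs_bf_one_sample,
                     median_split_battery, min_frequency_ratio,
                     power_one_sample_t, signed_rank_v, wilcoxon_one_sample)


def enumerate_signed_rank_p(values, mu0=0.0, tail="greater"):
    """Exact signed-rank p by brute-force enumeration of all sign patterns."""
    d = np.asarray(values, dtype=float) - mu0
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    v_obs = ranks[d > 0].sum()
    vs = []
    for signs in itertools.product((1, -1), repeat=len(d)):
        vs.append(ranks[np.array(signs) > 0].sum())
    vs = np.array(vs)
    p_ge = (vs >= v_obs - 1e-9).mean()
    p_le = (vs <= v_obs + 1e-9).mean()
    if tail == "greater":
        return p_ge
    if tail == "less":
        return p_le
    return min(1.0, 2 * min(p_ge, p_le))


class TestWilcoxon:
    def test_three_positive_values(self):
        rep = wilcoxon_one_sample([1.0, 2.0, 3.0], 0.0, tail="two-sided")
        assert rep.statistic == 6
        assert rep.p == pytest.approx(0.25)

    def test_v_maximum_when_all_positive(self):
        x = np.random.default_rng(0).uniform(0.01, 1.0, 50)
        assert signed_rank_v(x) == 50 * 51 / 2  # 1275

    def test_symmetric_values_at_null_mean(self):
        x = np.array([-2.0, -1.0, 1.0, 2.0])
        assert signed_rank_v(x) == 4 * 5 / 4

    @pytest.mark.parametrize("n", [5, 8, 12])
    @pytest.mark.parametrize("tail", ["greater", "less", "two-sided"])
    def test_exact_p_equals_enumeration(self, n, tail):
        rng = np.random.default_rng(100 + n)
        for _ in range(5):
            x = rng.normal(0.2, 1.0, n)
            rep = wilcoxon_one_sample(x, 0.0, tail=tail)
            assert rep.p == pytest.approx(
                enumerate_signed_rank_p(x, 0.0, tail), abs=1e-12)

    def test_degenerate_all_equal_mu0(self):
        rep = wilcoxon_one_sample([0.3, 0.3, 0.3], 0.3)
        assert rep.p == 1.0
        assert "degenerate" in rep.note

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0.3, 1.0, 60)
        rep = wilcoxon_one_sample(x, 0.0, tail="greater")
        assert rep.note == "normal approximation"
        assert 0 <= rep.p <= 1
        assert rep.ci_low < rep.mean < rep.ci_high


class TestBayesFactor:
    def test_quadrature_matches_cauchy_mixture_oracle(self):
        # independent oracle: BF10 = E_{delta~Cauchy(0,r)} nct(t; nu, delta
        # sqrt(n)) / t(t; nu), integrated on a fine grid
        rng = np.random.default_rng(4)
        x = rng.normal(0.5, 1.0, 5)
        n = len(x)
        t = x.mean() / (x.std(ddof=1) / np.sqrt(n))
        r = np.sqrt(2) / 2

        def num(delta):
            return stats.nct.pdf(t, n - 1, delta * np.sqrt(n)) \
                * stats.cauchy.pdf(delta, 0, r)

        from scipy.integrate import quad
        numerator = quad(num, -np.inf, np.inf, limit=400)[0]
        oracle = numerator / stats.t.pdf(t, n - 1)
        assert jzs_bf_one_sample(x) == pytest.approx(oracle, rel=1e-4)

    def test_null_sample_favours_null(self):
        # t exactly 0 at n = 50
        assert jzs_bf_one_sample(t=0.0, n=50) < 1

    def test_monotone_in_t(self):
        bfs = [jzs_bf_one_sample(t=t, n=20) for t in (0.0, 0.5, 1.0, 2.0,
                                                      3.0)]
        assert all(b2 > b1 for b1, b2 in zip(bfs, bfs[1:]))

    def test_reciprocal_identity(self):
        bf10 = jzs_bf_one_sample(t=1.7, n=30)
        bf01 = 1.0 / bf10
        assert bf10 * bf01 == pytest.approx(1.0)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            jzs_bf_one_sample([1.0, 1.0, 1.0])


class TestPower:
    def test_planned_design_reaches_080(self):
        assert power_one_sample_t(0.41, 50, 0.05, "two-sided") >= 0.80

    def test_null_effect_power_is_alpha(self):
        assert power_one_sample_t(0.0, 40, 0.05, "two-sided") \
            == pytest.approx(0.05, abs=1e-9)

    def test_matches_statsmodels(self):
        from statsmodels.stats.power import TTestPower

        for d, n in ((0.2, 30), (0.41, 50), (0.8, 12)):
            assert power_one_sample_t(d, n) == pytest.approx(
                TTestPower().power(effect_size=d, nobs=n, alpha=0.05,
                                   alternative="two-sided"), abs=1e-8)

    def test_monotone_and_z_limit(self):
        grid = [power_one_sample_t(d, 40) for d in (0.1, 0.3, 0.5)]
        assert grid == sorted(grid)
        ns = [power_one_sample_t(0.3, n) for n in (10, 40, 160)]
        assert ns == sorted(ns)
        n = 5000
        z = stats.norm.ppf(0.975)
        approx = stats.norm.sf(z - 0.05 * np.sqrt(n)) \
            + stats.norm.cdf(-z - 0.05 * np.sqrt(n))
        assert power_one_sample_t(0.05, n) == pytest.approx(approx, abs=5e-3)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            power_one_sample_t(0.4, 1)


class TestStimulusDesign:
    def test_packaged_ratio_floor(self, stimuli):
        ratio = min_frequency_ratio(stimuli)
        assert ratio == pytest.approx(107 / 15, rel=1e-9)
        assert ratio >= 7

    def test_zero_low_frequency_errors(self, stimuli):
        bad = stimuli.copy()
        bad.loc[(bad["word"] == "briller"), "frequency"] = 0
        with pytest.raises(ValueError):
            min_frequency_ratio(bad)


class TestFrequencyImbalanceCorrelation:
    def _item_scores(self, stimuli, noise=0.0, seed=0):
        ref = stimuli[stimuli["role"] == "referent"]
        imb = ref.groupby("pair_id")["frequency"].agg(
            lambda f: abs(f.iloc[0] - f.iloc[1]))
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "pair_id": imb.index,
            "score": 0.002 * imb.to_numpy()
            + noise * rng.normal(size=len(imb))})

    def test_proportional_effects_give_r_one(self, stimuli):
        out = freq_imbalance_correlation(self._item_scores(stimuli), stimuli)
        assert out["r"] == pytest.approx(1.0)
        assert out["n"] == 8

    def test_hand_covariance_formula(self, stimuli):
        item = self._item_scores(stimuli, noise=0.1, seed=3)
        out = freq_imbalance_correlation(item, stimuli)
        merged = out["pairs"]
        x = merged["freq_imbalance"].to_numpy()
        y = merged["score"].to_numpy()
        r_hand = (((x - x.mean()) * (y - y.mean())).sum()
                  / np.sqrt(((x - x.mean()) ** 2).sum()
                            * ((y - y.mean()) ** 2).sum()))
        assert out["r"] == pytest.approx(r_hand)
        assert out["bf10"] > 0

    def test_pair_order_invariance(self, stimuli):
        item = self._item_scores(stimuli, noise=0.1, seed=5)
        shuffled = item.sample(frac=1, random_state=1)
        r1 = freq_imbalance_correlation(item, stimuli)["r"]
        r2 = freq_imbalance_correlation(shuffled, stimuli)["r"]
        assert r1 == pytest.approx(r2)

    def test_too_few_pairs_errors(self, stimuli):
        with pytest.raises(ValueError):
            freq_imbalance_correlation(
                self._item_scores(stimuli).head(2), stimuli)


def _subject_scores(rng, n, effect=0.0):
    rows = []
    for i in range(n):
        for cond in ("context", "frequency"):
            for ttype in ("matching", "related"):
                rows.append((f"p{i:03d}", cond, ttype,
                             rng.normal(effect if ttype == "matching"
                                        else 0.0, 0.2)))
    return pd.DataFrame(rows, columns=["participant_id", "condition",
                                       "trial_type", "score"])


class TestMedianSplit:
    def test_split_boundary_230_goes_older(self):
        rng = np.random.default_rng(0)
        scores = _subject_scores(rng, 6)
        ages = pd.Series([200, 215, 229, 230, 250, 270],
                         index=[f"p{i:03d}" for i in range(6)])
        out = median_split_battery(scores, ages, split_days=230)
        out = out.set_index(["age_group", "trial_type", "condition"])
        assert out.loc[("older", "matching", "context"), "n"] == 3
        assert out.loc[("younger", "matching", "context"), "n"] == 3

    def test_empty_cell_skipped(self):
        rng = np.random.default_rng(0)
        scores = _subject_scores(rng, 4)
        ages = pd.Series([200, 210, 215, 220],
                         index=[f"p{i:03d}" for i in range(4)])
        out = median_split_battery(scores, ages)
        assert set(out["age_group"]) == {"younger"}


class TestMixedModels:
    def _pair_scores_frame(self, rng, n=30, slope=0.0, base=0.0):
        ages = rng.integers(184, 275, n)
        rows = []
        u = rng.normal(0, 0.05, n)
        for i in range(n):
            for cond in ("context", "frequency"):
                for pair in range(4):
                    for ttype in ("matching", "related"):
                        mu = (base + slope * (ages[i] - 229)
                              if ttype == "matching" else 0.0)
                        rows.append((f"p{i:03d}", f"{cond}-pair{pair}", cond,
                                     ttype, mu + u[i]
                                     + rng.normal(0, 0.25)))
        scores = pd.DataFrame(rows, columns=["participant_id", "pair_id",
                                             "condition", "trial_type",
                                             "score"])
        ages = pd.Series(ages, index=[f"p{i:03d}" for i in range(n)])
        return scores, ages

    def test_log_offset_maps_minus_one_to_zero(self):
        assert np.log(-1.0 + 2.0) == 0.0

    def test_detects_injected_age_slope(self):
        rng = np.random.default_rng(8)
        scores, ages = self._pair_scores_frame(rng, n=40, slope=0.004)
        rep = fit_age_model(scores, ages, include_trial_age_interaction=True)
        simple = rep.simple_effects.set_index("trial_type")
        # matching slope on the log scale is about half the score slope
        assert simple.loc["matching", "age_slope"] > 0
        assert simple.loc["matching", "p"] < 0.05
        assert abs(simple.loc["related", "age_slope"]) \
            < abs(simple.loc["matching", "age_slope"])

    def test_requires_two_infants_and_pairs(self):
        df = pd.DataFrame({"participant_id": ["a"] * 4,
                           "pair_id": ["x", "x", "y", "y"],
                           "condition": ["context"] * 4,
                           "trial_type": ["matching", "related"] * 2,
                           "score": [0.1, 0.0, 0.2, -0.1]})
        with pytest.raises(ValueError):
            fit_age_model(df, pd.Series([200], index=["a"]))


class TestComprehensionSplit:
    def _baseline(self, rng, n=12, constant_flags=False):
        rows = []
        quest_rows = []
        for i in range(n):
            pid = f"p{i:03d}"
            for cond, pair, word in (("context", "eple-fot", "eple"),
                                     ("frequency", "bil-sofa", "bil")):
                rows.append((pid, f"{pid}_{word}", cond, pair, word,
                             rng.normal(0.0, 0.3)))
                quest_rows.append((pid, 220, 1, word,
                                   5, 0 if constant_flags else int(i % 2)))
        base = pd.DataFrame(rows, columns=["participant_id", "trial_id",
                                           "condition", "pair_id",
                                           "target_word", "value"])
        quest = pd.DataFrame(quest_rows, columns=["participant_id",
                                                  "age_days", "list_id",
                                                  "word", "familiarity",
                                                  "cdi_understands"])
        return base, quest

    def test_constant_flags_drop_factor(self):
        base, quest = self._baseline(np.random.default_rng(0),
                                     constant_flags=True)
        out = comprehension_split_analysis(base, quest)
        assert "constant" in out["note"]
        assert not any("understood" in t for t in out["terms"]["term"])

    def test_two_level_factor_is_modelled(self):
        base, quest = self._baseline(np.random.default_rng(1))
        out = comprehension_split_analysis(base, quest)
        assert any("understood" in t for t in out["terms"]["term"])
        assert {"yes", "no"} == set(out["cells"]["understood"])
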