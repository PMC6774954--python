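# Methods

This note documents the models, conventions and numerical choices behind
`iplgaze`, in the package's own terms. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The design being analysed

The pipeline targets a within-subject two-picture preferential-looking
design: two blocks (context condition, frequency condition) of 16 trials
each, built from 4 picture pairs per condition. Each pair appears four
times — twice on *matching* trials (each object named once) and twice on
*related* trials (each object cued once by a contextually or
frequency-related word that labels neither picture) — with sides fully
counterbalanced: within each trial type every object appears once left and
once right, and across trial types every object is the target once per
side. Two presentation lists mirror all sides. Four single-picture control
trials (house/tree) check engagement. Trials give ~2000 ms of silent
exposure, then the carrier sentence; the target word onset is the anchor
for analysis windows and trials end 3500 ms after it (≈5.5 s total). Ages
span 184–274 days.

The packaged stimulus table carries the 32 Norwegian words (8 referent
pairs + 8 related pairs), their English glosses and child-directed-speech
(CDS) corpus frequencies. One related word (bathtub) has no corpus
frequency and is stored as missing. The design floor for the frequency
condition — the frequent referent of each pair is heard ≥7× more often
than its partner — is checked by `min_frequency_ratio` over the four
frequency-condition *referent* pairs (minimum 107/15 ≈ 7.13).

## Windows, AOIs and time accounting

* Pre-naming: [trial start, word onset). Post-naming: [onset + 367 ms,
  onset + 3500 ms] — 3133 ms long; the 367 ms offset allows for saccade
  programming after word recognition. Cluster window: [onset − 2000 ms,
  trial end), binned at 50 ms.
* AOIs are 800 × 680 px rectangles. Their placement is not part of the
  design spec, so the default centres each AOI in its half of the
  1920 × 1080 screen, at (480, 540) and (1440, 540); both are
  configurable. Rectangles are half-open, `[x0, x1) × [y0, y1)`, origin
  top-left.
* Looking time is **duration-weighted, not sample-counted**: each gaze
  sample covers the interval to the next sample, clipped to the analysis
  window and capped at the nominal inter-sample interval (a recording gap
  is lost time, not dwell). This makes every downstream quantity
  rate-agnostic — verified by a 30 vs 120 Hz invariance test — and means
  the pipeline is indifferent to whether the upstream tracker ran at 60 or
  300 Hz. Whether the original studies counted raw samples or interpolated
  durations is generally unreported; duration weighting is the
  self-consistent choice.

## Dependent variables

The central datum is the per-pair **difference in looking proportion**:
with P = t_target/(t_target + t_distractor) computed in the post-naming
window (neither-looks never enter the denominator),

    score(A, B) = P(looks at A | A named) − P(looks at A | B named),

bounded in [−1, 1], chance 0, and invariant to which pair member is called
A (P_B = 1 − P_A). A pair score exists only when both pair members survive
screening as targets. Because each word is targeted twice, the two
surviving presentations are pooled at the duration level before the
proportion is formed — this yields exactly one matching and one related
score per pair per infant, the unit the by-subject and by-item averages
expect. How the original analyses pooled repeat presentations is not
documented; duration-level pooling is this package's choice and is flagged
as such.

Baseline-corrected looking is (P_target − P_distractor)_post −
(P_target − P_distractor)_pre per trial, in [−2, 2], undefined (missing,
never zero) when a window has no AOI looking.

Binned series are target proportions on the 50 ms onset-locked grid;
missing bins stay missing (zero would bias toward the distractor). For
group analyses, trial series are averaged within participants per cell and
transformed with arcsin√p, whose chance level is arcsin√0.5 = π/4.

## Cluster-based permutation test

Per bin, a one-sample t across participants against π/4 (vs-chance) or a
paired t on the within-participant matching−related difference. Bins with
|t| > 2 form maximal contiguous same-sign runs; a missing bin breaks
contiguity (conservative). Cluster mass is Σt. The null is built by
participant-level sign flips about chance (equivalently condition-label
swaps for the paired comparison), recomputing the **maximum |mass| across
the whole window** per permutation — the max-statistic reading that gives
family-wise control; whether the original procedure compared signed or
absolute mass is unreported, and both are exposed (`two_sided_mass`).
p = (1 + #{null ≥ observed})/(1 + n_permutations) is never exactly zero;
with exhaustive enumeration (all 2ⁿ sign patterns, used as the oracle for
small n) the identity permutation plays the +1 role. Sign-flip
exchangeability is exact here because a proportion P that is symmetric
about 0.5 has arcsin√P symmetric about π/4 (arcsin√(1−p) = π/2 −
arcsin√p). Permutations flip whole participant mean series, not single
trials — the participant-level reading of "assigned randomly for each
participant"; whether the original procedure permuted at the trial level
is unreported.

## Inferential battery

* **Signed-rank test**: V is the R-style sum of positive-difference ranks
  after dropping exact ties with the null value (so V_max = n(n+1)/2; all
  50 values positive gives V = 1275). Exact p for n ≤ 25 without ties,
  else normal approximation with continuity correction. Zeros are dropped
  — the standard signed-rank convention; the original handling is
  unstated. Vs-chance tests default to one-tailed *greater* (comprehension
  predicts positive scores); two-sided is a flag.
* **Bayes factors**: one-sample JZS BF10, Cauchy(0, √2/2) effect prior,
  computed by quadrature over the Zellner–Siow inverse-gamma mixture and
  cross-checked in tests against an independent Cauchy-mixture quadrature
  and against pingouin. The BF is reported alongside V — i.e. computed
  from the same values via the t-based JZS form — mirroring the common
  practice of quoting `ttestBF`-style evidence next to nonparametric
  statistics. Correlation BFs come from pingouin's Pearson BF.
* **Confidence intervals**: two-sided t-based by default (symmetric, like
  the intervals such studies print); percentile bootstrap available.
* **Mixed models**: log(score + 2) — the +2 offset keeps the argument ≥ 1
  for scores in [−1, 1] — regressed on trial type, condition, their
  interaction and mean-centred age (days), with *crossed* random
  intercepts for infant and word pair fit as MixedLM variance components.
  statsmodels provides no Satterthwaite denominator df, so fixed effects
  are reported as Wald z with F ≈ z² against a normal reference; this is
  an approximation to the fractional-df F tests of dedicated mixed-model
  software and is labelled as such in the output. Simple effects re-fit
  per trial type. Baseline-corrected values equal to exactly −2 (post all
  on the distractor after pre all on the target) have no finite log and
  are dropped with a count, not clipped.
* **Median split** at 230 days: an infant aged exactly 230 days is in the
  older group. **Power** uses the noncentral t (ncp = d√n, df = n − 1).
  The frequency-imbalance correlation is Pearson r between per-pair mean
  scores and |Δ CDS frequency|, one-sided for a positive relationship.

## Screening conventions

Reasons are assigned in a fixed order (experimenter flag → no pre-naming
look → < 0.5 s post-naming AOI look → familiarity), one primary reason per
trial, so counts reconcile exactly. "No looking in the pre-naming period"
is read strictly as zero valid on-AOI samples pre-naming. The 0.5 s
criterion sums target + distractor AOI time ("at either image"), not
continuous dwell. The participant threshold is the operational count 6 (of
32) — note 6/32 = 18.75%, not the rounded 20% often quoted beside it. The
control check requires the infant's mean post-naming target proportion
over control trials to reach 0.5; the accompanying cohort-level test
defaults to a null of 0 (the convention in the engagement-check tradition,
odd as it is against a proportion) and the null is configurable rather
than silently harmonised.

## The synthetic cohort generator

Gaze is an alternating renewal process of AOI dwell bouts — exponential
durations (mean 800 ms), each bout placed on the target AOI, distractor
AOI or the midline gap — not an oculomotor model: the pipeline consumes
only AOI dwell, so saccade kinematics would add nothing testable. Before
onset + 367 ms the two pictures are equiprobable; afterwards target
occupancy is 0.5 + δ, where δ is set per (condition, trial type), may
carry a linear age slope (centred at 229 days), and receives mean-zero
per-infant (sd 0.03) and per-pair (sd 0.02) normal heterogeneity — the
ground truth behind the analysis model's random intercepts. The per-pair
score therefore has expectation 2δ. A constant per-infant left bias is
available (default 0) to exercise the counterbalancing.

Defaults are the study conditions: 50 infants, ages uniform on 184–274
days, 2 lists, 36 trials (32 experimental + 4 control), onset 2000 ms, end
5500 ms. The default effect is a small matching-only preference
(δ = 0.02) growing at 0.003/day — the age-graded shape the design is
meant to detect; all-null cohorts come from `EffectSpec.null()`.
Missingness: 10% whole-trial dropout, 8% i.i.d. sample loss, and a
3 × 10⁻⁵/ms fussiness hazard (the infant quits the trial), which together
lose roughly a quarter to a third of trials — the loss scale such studies
report. Familiarity ratings are skewed high with a 4% "never used" rate;
CDI "understands" flags are Bernoulli(0.2). Control trials use 0.93 target
preference with 90% away time before the prompt and 50% after it — the
re-orienting response to a named lone object — so every engaged infant
shows post-naming target looking and mean fixation lands near a quarter of
the trial. The default sampling rate is
60 Hz — a desk-scale stand-in for 300 Hz hardware that the rate-agnostic
accounting makes innocuous; it is configurable.

What the generator does **not** emulate: saccade latencies and main-
sequence kinematics, pupillometry, calibration drift, binocular
disagreement, autocorrelated familiarity across semantically similar
words, and any systematic condition difference in effect size. Passing
tests therefore certify the *pipeline* — its screening logic, estimators,
error rates and power — under a faithful abstraction of the data's AOI
structure, not the behaviour of real infants.

Ground truth (injected δ per trial, ages, list assignment, random
intercepts) is written to a separate `truth.json` sidecar that no analysis
stage reads; the pipeline consumes only the three data files.

## Validation experiments and problem sizes

`iplgaze.validation` runs the full chain over replicate cohorts:

* **Null calibration**: 20-infant all-null cohorts, 250 permutations;
  measures the one-tailed vs-chance signed-rank rejection rate and the
  cluster family-wise rate at α = 0.05. The test suite uses 500
  replicates; the reproduction script 300.
* **Effect detection**: the planted matching shift is calibrated from a
  200-infant null pilot so the by-subject effect size is d = 0.44
  (δ = d·sd/2, since the score mean is 2δ), then 23-infant cohorts
  (matching-only layout, missingness off so n stays fixed) are tested
  one-tailed; 500 replicates in the suite, 300 in the script. The rate
  should bracket the analytic noncentral-t power of d = 0.44 at n = 23.
* **Age-slope recovery**: δ = 0.04 matching effect with a 0.003/day slope,
  30-infant cohorts; the matching simple-effect 95% CI from the mixed
  model should cover the log-scale slope, which the small-δ linearisation
  puts at (2 × slope)/(2 + 2δ̄) ≈ slope itself. The ±δ curvature this
  linearisation ignores is an order of magnitude below the CI half-width
  at these sizes. 150 replicates in the suite, 120 in the script.

These replicate counts and cohort sizes are the package's chosen
desk-scale problem sizes; all are arguments.

## Known limitations

* Wald-based mixed-model inference is anticonservative for very small
  numbers of infants or pairs; at the sizes used here the calibration
  experiments bound the distortion.
* The exact signed-rank path requires tie-free data; ties fall back to the
  corrected normal approximation even at small n.
* Binocular merging is out of scope — input is one gaze point per
  timestamp. Proprietary tracker binaries are not read; export to the
  documented TSV first.
* The cluster test's per-bin t needs ≥ 2 participants with data per bin;
  sparse cells surface as missing bins, which (by the contiguity rule) can
  only shorten clusters, never lengthen them.
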