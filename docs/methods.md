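# Methods

## Problem

The WHO/ISH risk prediction charts estimate 10-year fatal or non-fatal
cardiovascular (CVD) risk as one of five ordinal bands (<10%, 10–<20%,
20–<30%, 30–<40%, ≥40%). Two variants exist for each WHO epidemiological
subregion: a low-information (LI) chart using gender, age, smoking,
diabetes and systolic blood pressure (SBP), and a high-information (HI)
chart that additionally stratifies on total cholesterol (TC). In India
the NPCDCS programme prescribes the SEAR-D charts and initiates
treatment (the T_HR group) when the band is ≥30%, or 20–<30% with
SBP strictly over 140 mmHg.

The package answers two questions on a screening cohort: (1) how often
and for whom do the LI and HI variants disagree, and what does that
disagreement cost at national scale if the LI chart over-initiates
treatment; (2) can a model using only pre-cholesterol information —
in its sparsest published form, the two-feature logistic score
`logit(c) = −5.6554 + 0.0416·age + 0.0132·SBP` — decide at point of
care whether a cholesterol test would change the subject's band.

## Chart tables

Chart content is a data resource (CSV, one row per cell), validated on
load for key-space completeness (LI 2·2·2·4·4 = 128 cells, HI 640),
duplicate keys and band labels, and audited for monotonicity along the
age, SBP and TC axes; violations are reported, never silently altered.

Binning follows the chart-usage conventions, half-open and closed on
the left: age decades 40/50/60/70 (≥70 on the 70 band); SBP <140 /
140–159 / 160–179 / ≥180 mmHg; TC integer-mmol/l bands <5, [5,6),
[6,7), [7,8), ≥8. TC converts at 38.67 mg/dl per mmol/l. Subjects
under 40 are scored on the 40 band and flagged rather than rejected —
screening cohorts contain them. Diabetes for chart input is the
reported history OR fasting glucose ≥ 126 mg/dl (configurable;
operational definitions vary between studies). Measured SBP is used
as-is for treated subjects (no back-correction).

### Synthetic stand-in tables

The published SEAR-D figures are colour charts without a deposited
machine-readable transcription, so the bundled tables
(`data/seard_charts_synthetic.csv`) are a synthetic stand-in, generated
by quantizing a latent logistic risk surface at a representative point
of each cell:

    logit(risk) = −3.0 + 0.09·(age−55) + 0.05·(SBP−140) + 0.42·(TC−5.5)
                  + 0.35·male + 0.55·smoker + 0.65·diabetes

with risk in (0,1) scaled to percent and cut at 10/20/30/40. The LI
table evaluates the surface at the reference cholesterol 5.5 mmol/l.
Coefficients were fixed once, at construction time, to reproduce the
structural geometry of the real charts rather than their absolute
values: the corner cells span the full band range; one decade of age,
and roughly one 20-mmHg SBP row, moves about one band near the
boundaries (the four SBP rows cross about three bands, matching the
steep pressure axis of the published charts); smoking and diabetes
each shift roughly one band. Because the surface is strictly monotone
and representative points are ordered, the tables are monotone by
construction, and LI/HI disagreement concentrates where band
boundaries are dense — older, higher-SBP subjects — which is the
structure the downstream analysis studies. Absolute band assignments
are NOT those of the published charts; any analysis needing the real
cells should load a transcription through the same resource format.

## Synthetic cohorts

The generator emulates a rural South-Indian screening subset
(N = 1066): gender-stratified means/SDs for age, SBP, DBP, glucose and
TC, smoking prevalences (40.6% male, 5.1% female), hypertension
treatment prevalences (13.8% / 14.8%), and male fraction 0.488.

Continuous factors are drawn from a Gaussian copula over truncated
normal marginals. The truncation bounds (age [30,90] y, SBP [80,230]
mmHg, DBP [50,130], glucose [50,400] mg/dl, TC [80,400], BMI [13,45])
would bias a naively truncated draw — the age bound sits only ~1.5 SD
from the mean — so the parent normal parameters are solved (2-D root
find on `scipy.stats.truncnorm` moments) such that the *truncated*
distribution has exactly the target mean and SD. Large-sample moments
therefore recover the configured values to Monte-Carlo error.

Latent correlations are not reported for the source study; defaults
are age–SBP 0.40, SBP–DBP 0.70, age–TC 0.20, age–glucose 0.15, others
zero — physiologically conventional values under which chart
disagreement lands in the low tens of percent and concentrates in
older, higher-SBP subjects. BMI (21.5±3.5 kg/m²), history-of-diabetes
(6%) and history-of-high-cholesterol (3%) prevalences are non-reported
defaults. Hypertension-treatment probability rises with measured SBP
(slope 0.04 logit/mmHg; intercept solved by quadrature over the SBP
marginal so the gender prevalence is preserved), and history flags
carry an odds ratio of 4 given an elevated corresponding measurement,
with the base rate solved to preserve the marginal prevalence.

What the generator does not emulate: the village/stratification
sampling design; joint structure of smoking with other factors beyond
gender (independence assumed); longitudinal outcomes; measurement
error and digit preference in field BP readings. Passing tests
therefore show that the pipeline recovers structure the generator puts
in, not that it would perform identically on the original study data.

## Disagreement analysis

Each subject is scored by both charts; the T_HR flag is computed per
variant from that variant's band and the subject's SBP. The summary
exposes both published disagreement denominators (the either-model
T_HR union, and the HI T_HR set alone). Significance of the ordinal
band shift uses a Friedman test for two related samples with tie
correction, implemented directly (library routines require k ≥ 3);
with all pairs tied the statistic is 0 and p = 1 by convention.

The discordant-subpopulation profile uses a two-sample two-sided
t-test for continuous features and a Wilcoxon rank-sum test for binary
ones (the rank-sum form is the correct unpaired test; a signed-rank
test does not apply to unpaired groups of different sizes).

The policy projection is pure arithmetic: population × fraction over
40 × fraction at high risk × fraction over-treated, costed at a daily
treatment price range × 30 days/month.

## Pre-screening models

The discordance label is predicted from 10 pre-cholesterol features
(gender, age, smoking, histories of diabetes/high cholesterol, BMI,
SBP, DBP, treatment status, glucose); nothing derived from TC may
enter. Data split 70:30, stratified; all tuning happens inside the
training set.

- **mRMR ranking.** Plug-in mutual information (bits) on discretized
  features; continuous features are quartile (equal-frequency, 4-bin)
  discretized, a robust choice at n ≈ 1000. The greedy criterion is
  mean relevance minus mean pairwise redundancy (1/|S|² over ordered
  pairs, self-pairs excluded so the singleton criterion equals
  marginal relevance). Ties break by column order.
- **L1 logistic regression.** 30-point log-spaced C grid from 10⁻³
  (effectively all-zero) to 10³ (effectively unpenalized); per fold of
  a 4-fold CV the best C by validation AUC is kept, the four winners
  are averaged on the log scale (C is multiplicative), and the model
  is refit at the averaged strength. Features are standardized
  internally; coefficients are reported on the raw scale.
- **Linear SVM.** C grid 2⁻⁵…2¹⁵ doubling, 4-fold CV on AUC of
  decision values, refit at the modal fold winner (tie → smaller C).
  The liblinear solver is used: for a strictly linear kernel it fits
  the same hyperplane family as a kernelized solver at a fraction of
  the cost at the top of the capacity grid.
- **Random forest.** Tree count {250, 500} × per-split candidate
  features {1,2,3,4}, chosen by out-of-bag (OOB) AUC. Variable
  importance is the OOB permutation importance (mean decrease in OOB
  accuracy when one feature is shuffled, averaged over trees), the
  randomForest-style measure. OOB probabilities also serve as the
  forest's training scores for threshold selection, since in-sample
  forest scores are near-perfect.

Thresholds maximize F_β (β = 1, 2, 3) over every distinct training
score cut; F_β ties resolve toward higher sensitivity. F_β with
precision = recall = 0 is 0 by convention. Sensitivity, specificity
and precision use the standard forms; undefined ratios return NaN
rather than raising. ROC/AUC are computed by descending-score sweep
with tie grouping and trapezoidal area (delegated to scikit-learn
behind the module surface); tests check AUC against an independent
pairwise Mann–Whitney count.

Model files are versioned JSON documents (kind, hyperparameters,
raw-scale coefficients or importances, thresholds, seed, training-set
hash). Linear models can be scored directly from the file; forest
files record the tuning needed to reproduce the ensemble from the
same data and seed rather than serializing it.

## Determinism and problem sizes

Every stochastic step takes an explicit seed (cohort draw, split, CV
fold shuffle, forest, permutation importance). The test suite runs the
end-to-end recovery checks on cohorts of n = 1066 (the study size)
across 10 seeds for the sparse-logistic check and single seeds for the
forest and SVM; generator calibration uses one n = 100 000 draw; the
parameter-recovery property uses n = 20 000 across 10 seeds. These
sizes make the full suite complete in well under a minute while
keeping Monte-Carlo error far below the asserted margins.

## Known limitations

- The bundled chart tables are synthetic; absolute bands and any
  statistic depending on them (e.g. the exact disagreement rate) are
  properties of the stand-in, not of the published charts.
- The published two-feature score is shipped as printed; it was fit to
  the original study data and is not refit here.
- Binary-feature group comparisons use the rank-sum test, which for
  0/1 data is equivalent to a proportion comparison with mid-ranks; no
  continuity correction is applied.
- No confidence intervals on AUC; no calibration analysis of the
  screeners.
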