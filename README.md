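# whoish-cvd

Chart-based cardiovascular risk stratification for the WHO South-East
Asian subregion D (SEAR-D), and a point-of-care pre-screen that decides
whether a total-cholesterol test would change the result.

The WHO/ISH risk prediction charts quantize 10-year CVD risk into five
ordinal bands (<10%, 10–<20%, 20–<30%, 30–<40%, ≥40%) from a handful
of risk factors. They come in two variants: the **LI** (low
information) chart uses gender, age, smoking, diabetes and systolic
blood pressure (SBP); the **HI** (high information) chart additionally
uses total cholesterol (TC). Under India's NPCDCS guidelines a subject
is treatment-eligible (**T_HR**) when the band is ≥30%, or 20–<30%
with SBP > 140 mmHg. Because a TC assay is often the most expensive
and least accessible part of screening, it matters *for whom* the two
variants disagree: only those subjects benefit from the test.

The package provides, for epidemiologists and screening-programme
planners:

- a validated, machine-readable chart engine (LI and HI lookup with
  documented binning conventions) — the bundled SEAR-D tables are a
  clearly-labelled synthetic stand-in with the structural geometry of
  the real charts, and real transcriptions load through the same format;
- the NPCDCS category and treatment-initiation rules;
- LI-vs-HI disagreement analysis: per-subject comparison, T_HR
  cross-tabulation, a tie-corrected Friedman test for the ordinal band
  shift, discordant-subpopulation profiling, and a national-scale
  over-treatment cost projection;
- the published two-feature pre-screening score

      logit(c) = −5.6554 + 0.0416·age + 0.0132·SBP

  where *c* is the probability that a TC test changes the subject's
  band, plus three trainable screeners (L1-regularized logistic
  regression, linear SVM, random forest with OOB tuning), mRMR feature
  ranking, and F_β-optimal threshold selection on ROC curves — all as
  scikit-learn-style estimators;
- a synthetic cohort generator reproducing the gender-stratified
  moments and prevalences of a rural South-Indian screening cohort
  (N = 1066), so every stage is exercisable without the original data.

See `docs/methods.md` for the model details and design choices.

## Worked example

```sh
whoish-cvd simulate --n 1066 --seed 1 --out demo
whoish-cvd compare --cohort demo/cohort.csv --out demo/cmp
```

prints

```
subjects scored:              1066
band disagreement:            125 (11.7%)
T_HR by LI chart:             120
T_HR by HI chart:             113
T_HR by both:                 104
T_HR by either:               129
T_HR disagreement:            25 (LI-only 16, HI-only 9)
  as % of either-model T_HR:  19%
  LI-only as % of HI T_HR:    14%
Friedman chi2 = 17.6720, p = 2.625e-05
```

Of 1066 synthetic subjects the two chart variants place 125 (11.7%) in
different risk bands — a highly significant ordinal shift — and
disagree on treatment initiation for 25 of the 129 subjects flagged by
either variant, with the LI chart over-initiating (16 LI-only vs 9
HI-only). The discordant subjects are markedly older and higher-SBP
than the cohort (see `demo/cmp/subpopulation_profile.csv`).

The published score, at point of care:

```python
>>> from whoish_cvd import poc_probability
>>> poc_probability(62, 141)   # 62 years, SBP 141 mmHg
0.2288
>>> poc_probability(45, 118)
0.0975
```

so a 62-year-old with SBP 141 has a 23% chance that measuring TC
changes their band, versus 10% for a 45-year-old with SBP 118; a
threshold chosen by maximizing F1 (balanced) or F3
(sensitivity-weighted) on training data turns this into a test/no-test
decision (`whoish-cvd screen --eq1 ...`).

Scaled to policy (`whoish-cvd project`, defaults: 1.252 billion
people, 29.4% over 40, 15% of those at high risk, 32% over-treated
under LI, INR 15–25/day):

```
aged over 40:        368.1 million
at high CVD risk:    55.2 million
over-treated (LI):   17.7 million
monthly cost range:  INR 8.0 to 13.3 billion
```

Training screeners on the chart-disagreement label:

```sh
whoish-cvd train --cohort demo/cohort.csv --learner rlr --seed 7 --out demo/model
whoish-cvd screen --cohort demo/cohort.csv --model demo/model/model_rlr.json --beta 3 --out demo/scr
```

On default synthetic cohorts the L1 logistic screener retains age and
SBP with positive coefficients, the forest ranks them as the top two
importances, and out-of-sample AUCs land in the mid-0.8s — the same
sparse age+SBP structure the published score encodes.

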