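# Methods

This note records the models, defaults, and numerical choices behind
`cytosurge`, in the order data flow through the pipeline.

## Cohort generative model

`simulate_cohort` emulates a two-arm longitudinal aging study. Subjects enroll
in 2007 (dates spread uniformly over the year): `n_young = 63` at ages drawn
uniformly from 20–31 y and `n_old = 72` from 60–96 y. Each of up to
`n_years = 9` annual visits occurs with probability `visit_prob = 0.9` (small
uniform date jitter, ±30 d). The log concentration of cytokine *k* for subject
*s* at visit time *t* is

```
log c[k,s,t] = b_k + u[s,k] + e[k,s,t] + surge(s,t)
```

- `b_k`: fixed panel baselines, geometrically spaced over 2–400 pg/mL (32
  analytes named after a standard inflammation panel);
- `u[s,k] ~ N(0, 0.5²)`: lognormal subject baselines, independent across
  cytokines. This makes the composite's subject-level ICC ≈ 0.3–0.5, which is
  what forces the subject-level testing choices below;
- `e ~ N(0, σ(age)²)` with `σ(age) = 0.3 + 0.05·age/10`: within-subject noise
  whose SD grows by 0.05 log-units per decade, producing the old-age
  variability gradient;
- `surge(s,t)`: zero unless the subject has a cancer event **and** is aged
  ≥ 80 at sampling. Within 4 years before diagnosis it ramps linearly from 0
  to `surge_peak_log_effect = 1.0` natural-log units at diagnosis, then decays
  exponentially with a 1-year half-life (a piecewise shape chosen as the
  simplest curve that peaks at diagnosis and falls thereafter, e.g. with
  resection). The peak is shared by all cytokines (per-cytokine multipliers
  default to 1); its size is a placeholder for parameter-recovery testing, not
  an estimate of any real effect.

Clinical events are drawn year by year from age-piecewise hazards (per-year
rates): cancer 0.002 / 0.02 / 0.08 below 60 / 60–80 / 80+, split 70/25/5%
into NMSC / invasive / other; cardiovascular, inflammatory, and other events
have their own piecewise rates. One cancer per subject by default
(`allow_recurrence` permits more, with a 2-year gap). Concentrations below
the detection limit (0.05 pg/mL) floor at half the limit and are flagged —
the standard immunoassay convention. Everything injected (event times,
per-sample surge, censoring flags) is returned as ground truth.

What the generator does **not** emulate: correlated subject effects across
cytokines (real panels share latent inflammatory tone, so real ICCs run
higher), assay batch effects and drift, informative missingness, covariates
such as BMI or blood pressure, and death/dropout. Passing tests therefore
demonstrate statistical correctness of the pipeline under the stated
structure, not robustness to those real-data features.

## Composite and outliers

The default composite is the geometric mean then standardization:
`raw = exp(mean_k log c_k)` over observed cytokines (pairwise deletion with
re-normalization; samples with under half the panel observed are excluded),
then `z = (log raw − mean) / sd` across all scored samples. The alternative
(`per_cytokine_z_mean`) z-scores each cytokine's log first, averages, and
re-standardizes; both are exposed because the order of standardization is a
genuinely open choice, and both are scale- and permutation-invariant.
Outliers: robust z against median and normal-consistent MAD, two-sided normal
p, BH across samples, flag at q < 0.05; MAD = 0 falls back to the SD.

## Repeated measures and test units

Subjects contribute up to nine samples whose composites are correlated
through `u[s,·]`. Rank tests that treat samples as exchangeable are
anti-conservative under this clustering, so wherever groups mix samples from
overlapping subject sets the package tests subject-level units:

- diagnosis-window association: per-(subject, window-status) mean composites
  (`units='sample'` remains available; reported N is the sample count);
- per-cytokine variance trend: Levene-type statistic on per-subject mean
  absolute deviations from the bin median;
- trajectory CIs: the bootstrap resamples subjects, not samples.

Matched per-cytokine tests are already paired (case sample vs its matched
naive control), so they rank pairs directly: greedy nearest-age matching
within sex and calendar-year strata, tolerance ±5 y, case order shuffled by
the run seed, controls used at most once, Wilcoxon signed-rank with Pratt
zero handling, BH across the 32 cytokines.

## Trajectories and onset

Loess = locally weighted linear regression with tricube weights (no
robustifying iterations), evaluated on a 0.25-year grid over the observed
relative-time range. The 95% CI is the pointwise 2.5–97.5 percentile band of
subject-bootstrap refits (default 200–300 replicates; the band is widened, if
needed, to contain the point fit). The baseline is the mean composite of
never-diagnosed subjects in the same age range plus samples at least 5 years
before diagnosis — the same pool the prediction stage uses as negatives.
Onset is the earliest grid time `t* < 0` with the CI's lower bound above the
baseline at every grid point in `[t*, 0]`.

**Span.** The default span is 0.4. With ~9 years of follow-up and a 4-year
linear ramp, wider smoothing windows (e.g. 0.75) bleed the ramp into the flat
pre-onset region and systematically detach the CI a year or more too early;
span 0.4 recovers a –4-year onset with median –4.1 y across simulated
cohorts. Span is a parameter wherever trajectories are fit.

**Known limitation.** Under the null (no surge), onset detection returns
"none" in ~91–92% of simulated cohorts rather than ≥95%: with ~25 subject
clusters the percentile bootstrap undercovers slightly at the boundary, and
occasional cohorts are elevated near diagnosis by chance. The false
detections are marginal, short detachments just before t = 0. Alternative
constructions (normal/t intervals from the bootstrap SD, BCa, robust loess)
measured within 92–94% and traded away onset-recovery accuracy, so the
plain percentile band is kept and the residual false-onset rate is documented
here rather than hidden.

## Tissue arm

Scores are `mean log2(TPM + 1)` over the gene set's genes present in the
matrix (pseudo-count 1; absent genes dropped with a log line). The early-stage
filter keeps stages 1–2; type inclusion keeps cancer types with strictly more
than 10 samples at ≥ 80 y. The standardized difference within a type is the
OLS coefficient of the age-group indicator (adjusted for sex; collinear or
constant confounders dropped) divided by the residual SD — Cohen's d when no
confounders remain — with the SE propagated on the same scale. Pooling is
fixed-effect inverse-variance (DerSimonian–Laird random effects behind a
flag), with Cochran's Q reported. Correlations (CDKN1A vs the set score) are
Spearman within type, Fisher-z transformed with SE `1/√(n−3)`, pooled, and
back-transformed; an under-80 restriction checks age independence. Gene-set
enrichment is competitive: rank-sum of in-set vs out-of-set per-gene pooled
effects, signed by the median difference, BH across sets — note that decoy
sets can rank significantly *below* a background that contains truly affected
genes; only positive enrichment of a null set would indicate miscalibration.
The age-bin analysis contrasts each 5-year bin from 60 up (open-ended 85+)
with the under-60 reference, per type, then pools across types per bin.

The tissue generator plants: per-(gene, type) intercepts; a log2 shift on the
18-gene cytokine set for samples ≥ 80 y sized so the score-level standardized
difference equals `effect_80plus = 0.6` (or a linear age trend from 60 y for
the contrast scenario); and a latent standard-normal inflammation axis loaded
on CDKN1A (3σ) and on the set genes with a loading solved so the
CDKN1A-score correlation hits `cdkn1a_coupling = 0.5` (|coupling| < 0.94 for
this geometry). Default sizes: four cancer types × (100 under-60 reference,
40 per 5-year bin 60–79, 25 at 80–84, 15 at 85+), echoing a pan-cancer
early-stage collection where 80+ samples are the scarce stratum; decoy genes
(60) carry no age effect.

## Prediction

Lead-time bins are half-open toward diagnosis, `(−k, −k+1]`, with the final
bin `(−1, 0)` open at 0 (a same-day sample is post-diagnostic and excluded);
a sample exactly 5 years before diagnosis is a negative, as are all samples
of cancer-naive subjects. AUROC is the rank (Mann–Whitney) formulation with
ties counted one half; the 95% CI is a percentile bootstrap stratified by
label. Sample-level units are the default (a subject may contribute several
samples); a subject-level variant (max composite per subject) is available as
a sensitivity check.

## Numerical and degenerate-input conventions

Dates are ISO-8601; relative times are days/365.25. Category synonyms live in
an editable text resource (`data/category_synonyms.tsv`). Ties between two
equidistant events break toward the earlier event. Identical paired SDs give
p = 1 rather than a refusal; an all-identical pre-diagnostic block refuses to
label states; a zero-cell contingency reports an infinite odds ratio; MAD = 0
falls back to SD; attribution shares clip to [0, 1] and report NaN on a
nonpositive denominator. Problem sizes in the test and acceptance runs (50
replicate cohorts for calibration/recovery suites, 40 in the acceptance
script, bootstrap 200–300) were chosen so each replicate exercises the full
pipeline at the default study scale.
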