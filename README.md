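# cytosurge

Analysis pipeline for longitudinal serum-cytokine surveillance: does systemic
inflammation rise *before* a cancer diagnosis, in whom, and how early?

The package is aimed at biostatisticians and immunologists working with
annual-visit multiplex cytokine panels (Luminex-style, pg/mL) alongside
clinical event records, plus an annotated tumor expression matrix for the
tissue counterpart. It implements, end to end:

- **Composite scoring.** The *serum cytokine abundance* of a sample is the
  standardized geometric mean of its panel,
  `z(mean_k log c_k)`, with outliers called against a robust normal null
  (median/MAD center-scale, Benjamini–Hochberg FDR).
- **Diagnosis-window association.** Samples are aligned to each subject's
  nearest event per category; the composite inside the ±2-year window is
  compared with the outside pool by Wilcoxon rank-sum on subject-level units,
  and the cancer-window's contribution to old-age variance is quantified as
  `(V_old − V_old\excl) / (V_old − V_young)`.
- **Pre-diagnostic states.** Samples within 2 years before a cancer diagnosis
  are clustered (Euclidean, complete linkage, k = 2) into inflamed vs
  non-inflamed; the age dependence is a subject-level 2×2 odds ratio with
  Fisher's exact test, plus sex/year/age-matched per-cytokine tests.
- **Surge trajectories.** Loess (tricube, degree 1) of the composite against
  time relative to diagnosis with a subject-bootstrap 95% percentile CI;
  *onset* is the earliest pre-diagnosis time from which the CI stays above the
  baseline mean through diagnosis.
- **Tissue meta-analysis.** Per-sample *tissue cytokine abundance* =
  mean log2(TPM+1) over the cytokine gene set; per-cancer-type standardized
  differences (OLS-adjusted, ≥80 vs <80) pooled by inverse variance; CDKN1A
  coupling meta-analysed on the Fisher-z scale; competitive gene-set
  enrichment; 5-year age bins against an under-60 reference.
- **Prediction.** Lead-time bins toward diagnosis in the 80+ group, rank-sum
  tests vs the negative pool, and the Mann–Whitney AUROC of the composite with
  a stratified bootstrap CI.
- **Synthetic generators.** `simulate_cohort` and `simulate_tissue` create
  ground-truthed inputs with the study's structure: two age strata (63
  enrolled at 20–31 y, 72 at 60–96 y), up to 9 annual visits, 32 cytokines
  with lognormal subject baselines, age-escalating event hazards, and an
  injectable surge — a linear log-scale ramp starting 4 years before a cancer
  diagnosis, restricted to subjects aged 80+ at sampling, decaying
  exponentially after diagnosis.

## Worked example

```python
import cytosurge as cs

panel, events, truth = cs.simulate_cohort(cs.CohortSimParams(seed=1))
scores = cs.composite_score(panel)

labels = cs.assign_lead_time(panel, events, age_threshold=80.0)
print(cs.group_tests(scores, labels)[["bin", "n", "p_value"]])
res = cs.bin_auroc(scores, labels, bins=["(-1,0)"], reps=1000, seed=1)
print(f"AUROC {res['auroc']:.2f} ({res['ci_low']:.2f}-{res['ci_high']:.2f})")
```

prints

```
       bin   n       p_value
0  (-5,-4]   8  8.305359e-01
1  (-4,-3]  13  1.657944e-03
2  (-3,-2]  15  1.086526e-09
3  (-2,-1]  18  4.500116e-12
4   (-1,0)  24  4.040627e-15
AUROC 1.00 (1.00-1.00)
```

Reading it: among 80+ samples, the composite of samples drawn 4–5 years
before a diagnosis is indistinguishable from the negative pool, significance
grows monotonically as sampling approaches diagnosis, and the final-year
samples are essentially perfectly separable — the injected pre-diagnosis
surge read back through the full pipeline. The `examples/` directory walks
through every stage the same way (simulation, composite and outliers, window
association, state clustering, trajectories and onset, tissue meta-analysis,
prediction).

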