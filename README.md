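# immunocyt

Immune-landscape analysis for bulk tumor expression cohorts: per-sample
immune scoring, median-split group comparison, gene-set enrichment, and
censored survival analysis, with a synthetic cohort generator that makes the
entire chain testable end to end without any external download.

The package is aimed at computational oncology work of the kind done on
TCGA-style cohorts: a gene × sample TPM matrix, per-sample copy-number
segment tables, a clinical table with several censored endpoints, and
repertoire summaries, from which one asks whether "immune-hot" tumors —
those with high cytolytic activity — differ in mutagenic programs, genomic
stability, antigen presentation, receptor diversity, checkpoint expression
and, ultimately, survival.

## The scores and models

- **Cytolytic activity (CYT)** — the geometric mean of granzyme A and
  perforin expression in TPM, `CYT = √(GZMA · PRF1)` (computed in log space
  with a configurable pseudocount, default 0.01). The cohort is split at the
  median: *high* means strictly above, so a tie-free cohort of 371 samples
  always yields 185 high / 186 low.
- **Panel scores** — APOBEC3 mutagenesis (7 cytidine-deaminase genes) and
  the inhibitory checkpoint index (11 exhaustion markers: PD-1, PD-L1,
  CTLA4, IDO1/2, LAG3, TIM3, PD-L2, TIGIT, ADORA2A, VISTA), each the mean of
  `log2(TPM + 1)` across the panel.
- **SCNA events** — the count of copy-number segments whose log2 segment
  mean is ≥ +0.6 (gain) or ≤ −0.4 (loss), boundaries inclusive.
- **Repertoire** — TCR/BCR richness (unique clonotypes) and CPK diversity
  (clonotypes per kilo-read: `1000 · unique CDR3 / total TCR reads`).
- **Group comparison** — Mann-Whitney U for continuous features (exact by
  full enumeration when the combined n ≤ 12, tie-corrected normal
  approximation otherwise) and Pearson chi-square for categorical ones; all
  p-values two-sided.
- **Gene-set enrichment** — signal-to-noise ranking between the score-high
  and score-low groups, the weighted Kolmogorov–Smirnov running-sum
  enrichment score ES ∈ [−1, 1], permutation-based NES and nominal p
  (gene-set or phenotype permutations), and ratio-of-tails FDR over the
  pooled normalized null.
- **Survival** — Kaplan-Meier product-limit curves with Greenwood standard
  errors and log-log median CIs (`NR` marks bounds never reached); k-group
  log-rank tests; Cox proportional hazards fit by damped Newton iterations
  on the partial likelihood (Efron tie correction by default, Breslow
  optional) with Wald CIs; and the clinical two-stage workflow in which
  every candidate covariate is screened univariately at α = 0.05 and the
  selected set (whole factors, if any level is significant) is refit
  jointly.

The synthetic generator plants a latent immune-heat factor *h* driving all
modalities in the directions above, plus an independent exhaustion axis *e*
that raises checkpoint expression and the hazard, so that the
score-high/exhaustion-low stratum fares best and score-low/exhaustion-high
worst even though checkpoint markers are marginally higher in score-high
tumors. See `docs/methods.md` for the full model and its limitations.

## Worked example

```bash
python examples/03_survival.py
```

```
CYT-high: n=185, median OS = 109.7 months, 95% CI (75.3, 195.9)
CYT-low: n=186, median OS = 53.0 months, 95% CI (45.1, 63.7)
log-rank: chi2 = 12.59, p = 0.000388

univariate screen (selected candidates):
 candidate    covariate    hr     p
til_status til_positive 0.704 0.029
 cyt_group     cyt_high 0.562 0.000

multivariate model:
   covariate    hr  ci_low  ci_high     p
til_positive 0.834   0.596    1.166 0.287
    cyt_high 0.597   0.425    0.840 0.003
```

A synthetic cohort of 371 patients with a planted protective immune effect:
score-high patients live roughly twice as long at the median, the log-rank
test rejects equality, and after joint adjustment the CYT group remains an
independent protective factor (HR ≈ 0.6, i.e. a ~40% lower death rate),
while TIL positivity — correlated with the same latent heat — loses
significance once CYT is in the model. The other scripts in `examples/`
walk through scoring, group comparisons, enrichment and the one-call
pipeline (`immunocyt run --simulate 371 --seed 0 --outdir immunocyt_out`).

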