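# Methods

This note records the statistical procedures the package implements, the
generative model behind its synthetic cohorts, the numerical conventions,
and the design choices made where more than one reasonable convention
exists. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Immune scores

**Cytolytic activity (CYT).** For each sample,
`CYT = exp(mean(ln(TPM_g + c)))` over g ∈ {GZMA, PRF1}. With pseudocount
c = 0 this is the plain geometric mean and is exactly 0 whenever either
gene is 0. The default c = 0.01 prevents `ln 0` while perturbing typical
TPM values (tens to hundreds) by well under 1%. The pseudocount is part of
the score definition, is configurable, and is recorded in every serialized
score frame.

**Panel scores.** The APOBEC3 score and the inhibitory checkpoint index are
the mean of `log2(TPM + 1)` across their panels (7 APOBEC3 genes; 11
checkpoint markers). Log base 2 with pseudocount 1 is the package's declared
convention — "log average expression" admits several readings, so base and
pseudocount are written into the output header for provenance. Protein-name
aliases (PD-1→PDCD1, PD-L1→CD274, TIM3→HAVCR2, PD-L2→PDCD1LG2, VISTA→VSIR)
are resolved through one explicit table; there is no fuzzy matching. A
second, four-marker panel (PDCD1, CTLA4, CD274, LAG3) is provided for
per-marker survival stratification.

**Median dichotomization.** `high ⇔ value > median`, ties to `low`. On
tie-free data this gives ⌊n/2⌋ high and ⌈n/2⌉ low — hence the
deterministic 185/186 split at n = 371. The direction of the tie rule is
the one that reproduces that split with the larger group labeled low.

**SCNA events.** A segment qualifies when its log2 segment mean is ≥ +0.6
or ≤ −0.4, boundaries inclusive; the per-sample statistic is the **count**
of qualifying segments. The phrase "sum of the segment mean changes" could
also be read as summing magnitudes; that reading is available behind
`mode="sum_magnitude"` but is never the default, because the quantity is
reported as a number of events. SEG coordinates are treated as 1-based
inclusive throughout; no interval arithmetic is ever performed on them —
only the segment means are thresholded.

**Repertoire.** Richness is the unique clonotype count as given; CPK
multiplies unique CDR3 clonotypes per read by 1000. CPK is undefined (an
error, not 0) when the read count is 0.

## Group comparisons

Mann-Whitney U is `#{x_i > y_j} + ½·#ties`, computed from midranks. For
combined n ≤ 12 (mode `auto`) the two-sided p is exact by enumerating all
C(n, n_x) group assignments and counting |U − μ| at least as large as
observed. Otherwise a normal approximation with tie-corrected variance and
a 0.5 continuity correction is used; it agrees with scipy's asymptotic
two-sided p to machine precision. For the 2v2 and 2v3 layouts the
approximation's worst-case deviation from enumeration provably exceeds
0.05, which is precisely why `auto` enumerates there. Chi-square is the
Pearson r×c statistic without continuity correction, df = (r−1)(c−1). No
multiple-testing adjustment is applied across score panels by default; raw
p-values are reported (FDR can be added downstream).

## Survival analysis

**Kaplan-Meier.** Product-limit estimator over distinct event times with
Greenwood variance. The median is the first event time with S ≤ 0.5; its
95% CI comes from the log(−log S)-transformed band (lower bound where the
lower confidence curve first crosses 0.5, upper bound where the upper curve
does). Bounds the curve never crosses are reported with the string sentinel
`NR`, never as a numeric infinity.

**Log-rank.** The k-group statistic sums observed-minus-expected deaths
with hypergeometric variance over event times and refers (O−E)ᵀΣ⁻(O−E) on
k−1 groups to chi-square with df = k−1. With two groups this equals the
squared standardized O−E statistic.

**Cox proportional hazards.** The partial likelihood is maximized by
Newton's method with step-halving (a step is accepted when the
log-likelihood does not decrease beyond a tolerance scaled to its
magnitude, so float noise near the optimum never blocks the quadratic
regime). Efron's tie correction is the default — follow-up recorded at
months resolution ties heavily — with Breslow behind a flag; both match R's
`survival::coxph` and (for Efron) lifelines to ~1e-7. Convergence requires
max|score| < 1e-8 within 100 iterations; a monotone likelihood (complete
separation) is reported as `converged=False`, never silently. Constant or
collinear covariates raise a singularity error before fitting. CIs are Wald
(`exp(β ± 1.96·se)`).

**Covariate selection.** Each candidate (age; sex; stage as II/III/IV
indicators vs I; etiology vs none; inflammation vs none; TIL vs negative;
score group vs low) is first fit alone on all samples with that candidate
and the endpoint observed. A candidate enters the joint model when **any**
of its level indicators reaches Wald p < α (default 0.05) — a multi-level
factor is kept or dropped whole, so a factor with one significant level
carries its non-significant levels along. The selected set is refit
jointly on the samples complete for all selected covariates. Missing
clinical values are a first-class category and are dropped per-analysis,
never imputed.

**Two-factor stratification.** Crossing two median-split scores yields four
strata (`high/high` … `low/low`); empty cells are omitted with a warning and
the log-rank df shrinks accordingly. Orderings are compared by restricted
mean survival time up to the smallest per-group maximum event time.

## Gene-set enrichment

Genes are ranked by signal-to-noise on `log2(TPM+1)`:
`(μ_high − μ_low) / (σ_high + σ_low)`, each group σ floored at
`max(min_sd, 0.2·|μ|)` so near-constant genes cannot dominate; ties break
lexicographically, making the ranking deterministic. Walking the ranked
list, a member of the set ("hit") adds `|metric|^w / Σ_hits |metric|^w` and
a non-member subtracts `1/(N − N_hits)`; the ES is the signed extremum of
the walk (which ends at 0 by construction, asserted to 1e-12). The default
weight is 1 (the classic weighted statistic); weight 0 is retained because
its walks are hand-checkable. The leading edge is the hits at or before the
extremum (at or after, for negative ES).

Significance: `n_perm` null ES values come either from random equal-size
member sets (`gene_set`) or from shuffled phenotype labels with full
re-ranking (`phenotype`); `auto` picks phenotype when both groups have ≥ 7
samples. NES divides ES by the mean |null ES| of matching sign; the nominal
p is the add-one-corrected fraction of same-sign null ES at least as
extreme; the FDR q across a collection is the classic ratio-of-tails over
all sets' pooled normalized nulls, reported alongside — never instead of —
the nominal p. Set members absent from the expression matrix are dropped
with a logged count. Fewer than 100 permutations is a configuration error.

## The synthetic cohort generator

Each sample i carries two independent standard-normal latents: immune heat
h_i and an exhaustion residual e_i. Per modality:

- **Expression**: `log2(TPM+1) = baseline + λ·h + γ_e·e + N(0, σ)`,
  back-transformed as `max(2^x − 1, 0)`. Loadings λ: 1.0 for GZMA/PRF1 and
  HLA-A/B, 0.7 for the APOBEC3 genes, 0.8 for checkpoint markers; γ_e = 1.0
  on checkpoint markers only; σ = 0.6. Baselines (log2 scale): 4.0
  cytolytic, 3.5 APOBEC3, 3.0 checkpoint, 8.0 HLA; 200 decoy genes with
  per-gene baselines uniform in [2, 8] and no latent loading.
- **Copy number**: the event count is Poisson with log-mean
  `log(20) − 0.3·h` (hot tumors are genomically quieter), realized as that
  many segments drawn beyond the ±(0.6/−0.4) thresholds plus three neutral
  segments.
- **Repertoire**: unique TCR CDR3 clonotypes `max(0, 800 + 150·h)` over a
  fixed 100,000 reads; BCR clonotypes scale the same slope by the base
  ratio.
- **Survival**: event times are exponential with hazard
  `λ0 · exp(−0.5·h + 0.6·e)` per endpoint, λ0 = 0.00845/month for death
  endpoints (median ≈ 82 months at h = e = 0) and twice that for
  progression endpoints; censoring is an independent exponential tuned to a
  60% censored fraction (non-informative, matching the KM/Cox assumptions).
  Times are rounded to 0.1 months, deliberately planting ties.
- **Clinical**: age ~ N(59.5, 13.5²) clipped to [18, 95]; sex 67% male;
  stage/inflammation/etiology drawn from fixed hepatocellular-carcinoma-like
  marginals with realistic missingness (stage 6.5%, inflammation 37%,
  etiology 5%); TIL positive with probability `logistic(1.0·h)`.

Two axes rather than one: a single heat factor reproduces every *marginal*
sign pattern, but it cannot make the score-low/exhaustion-high stratum the
worst-surviving one — under one factor, exhaustion-high always means hotter
and therefore better. The independent exhaustion residual, loading on
checkpoint expression and harming the hazard, is the minimal structure in
which exhaustion markers are higher in score-high tumors *and* exhaustion
net of heat is detrimental, which is the pattern the two-factor
stratification is designed to detect. The axis magnitudes (γ_e = 1.0,
hazard loading +0.6) were fixed while verifying that the generator plants
that ordering unambiguously, before the statistical test suite was run.

Each modality consumes an independent child stream of the seed, so the
clinical draws do not depend on how many copy-number segments were
realized; `null_config` zeroes every loading for type-I-error calibration.
The generator emulates the *statistical structure* of a real cohort, not
its content: no read-level data, no CDR3 sequences, no genome-positioned
SCNA hotspots, no gene-gene correlation beyond the two latent axes, and
exponential (proportional-hazards-true) survival. Passing tests therefore
demonstrate that the pipeline detects planted structure of the stated kind
and calibrates correctly under its absence — not that any particular real
cohort exhibits that structure.

## Problem sizes

The test suite and acceptance script use cohorts of 200–400 samples, 500
replicates for calibration and coverage checks, 100 seeds for direction
reproduction, 50 seeds at 1000 permutations for enrichment power, and
n = 2000 for Cox recovery — sizes at which the checked properties are
stable while a full run completes in a few minutes on one CPU.

## Known limitations

- The checkpoint index's membership and aggregation are declared
  conventions; other marker subsets or weightings are plausible.
- The exact Mann-Whitney mode enumerates C(n, n_x) assignments and is
  intentionally capped at combined n = 12.
- Cox standard errors assume the usual asymptotics; no robust (sandwich)
  variance, time-varying covariates, proportionality diagnostics or
  competing-risk machinery is provided.
- GSEA phenotype permutations re-rank the full matrix per shuffle, which is
  the expensive path; gene-set permutations are the default fallback for
  small groups.
- Readers require pre-collapsed gene symbols; identifier versioning and
  multi-mapping are out of scope.
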