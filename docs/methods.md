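# Methods

This note documents the statistical procedures implemented in
`pnetcohort`, their assumptions, the defaults and why they were chosen,
and what the synthetic-cohort tests do and do not demonstrate.

## Cohort harmonization

Pooling targeted-sequencing studies requires a common gene space and one
observation per patient.

- **Panel intersection.** Analyses are restricted to the set intersection
  of the contributing panels (e.g. a 341-gene and a 450-gene clinical
  panel intersect in 261 genes); genes absent from any panel are not
  evaluable in every patient and would bias pooled frequencies downward.
- **Nonsynonymous filter.** Only protein-altering variant classes are
  kept. The set is the conventional MAF grouping — Missense, Nonsense,
  Nonstop, Frame_Shift_Del/Ins, In_Frame_Del/Ins, Splice_Site,
  Translation_Start_Site — and is configurable. Unknown
  `Variant_Classification` strings are flagged, never silently dropped.
- **Eligibility.** Patients are excluded when any histology or
  differentiation field contains "carcinoma" (case-insensitive substring)
  or any sample is grade G3; neuroendocrine carcinoma is a biologically
  distinct, aggressive entity whose inclusion would contaminate the
  well-differentiated cohort. Patients with *unknown* grade or
  differentiation are retained: incomplete histopathology is the norm in
  aggregated registries, and excluding unknowns would bias the cohort
  toward the best-annotated studies.
- **Representative sample.** For multi-sample patients the sample with
  the highest nonsynonymous TMB is kept. TMB is the raw count of
  qualifying variants within the intersected panel (not per-megabase):
  it is used only to rank a patient's own samples, so a normalizing
  constant cancels. Ties break to the lexicographically smallest
  sample identifier — an arbitrary but deterministic and auditable rule.
  Whether TMB should be computed before or after panel restriction is
  genuinely open; this implementation counts within the panel so that the
  ranking uses exactly the variants the analysis will see. Patients whose
  samples have no mutation records are dropped with a warning unless the
  run declares all clinical samples sequenced (`assume_sequenced`), in
  which case they contribute all-zero rows — a sample can genuinely carry
  no nonsynonymous panel variant, and discarding such patients would
  inflate every frequency.
- **Cohort matrix.** The result is a binary patient × gene indicator
  (≥ 1 qualifying variant → 1) with a primary/metastasis stratum label.
  Multiplicity within a gene is deliberately discarded; all downstream
  statistics are presence/absence statistics.

## Frequencies, penetrance, and stratum tests

Frequencies are exact proportions mutated/total per gene per stratum. A
gene is *penetrant* when its frequency reaches 5% in at least one
analyzed stratum (the boundary is inclusive). The threshold scope is
configurable (`any_stratum`, the default, or `pooled`); the or-rule is
the default because a gene enriched only in metastases is exactly the
kind of signal a lesion-type comparison must not discard.

Two-stratum comparisons use a 2×2 mutated/wild-type × stratum table.
Fisher's exact test (two-sided, by the conventional
sum-of-probabilities-≤-observed definition) is selected whenever any
expected cell count is below 5, otherwise Pearson's χ² without
continuity correction; the choice is recorded per gene so it is
auditable. Tables with a zero margin are degenerate and report p = 1
with a flag. Multiplicity is handled with the Benjamini–Hochberg
step-up, computed by `statsmodels.multipletests` and cross-checked in the
test suite against an independent sorted-cumulative-minimum oracle.

## Pairwise exclusivity / co-occurrence

For each unordered pair of penetrant genes within a stratum, the 2×2
co-mutation table (both, A-only, B-only, neither) yields:

- Fisher two-sided p;
- odds ratio, with the Haldane–Anscombe +0.5 correction applied to all
  cells when any cell is zero;
- a signed statistic `z = s · Φ⁻¹(1 − p/2)`, where `s = +1` if the
  observed co-mutant count is below the independence expectation
  (row margin × column margin / n) — mutual exclusivity — and `s = −1`
  otherwise — co-occurrence. The implementation uses the upper-tail
  inverse survival function so tiny p-values do not underflow, and p is
  clamped at 1e-300 before the transform. Degenerate margins (a gene
  mutated in none or all patients of the stratum) report z = 0, flagged.

This signed-probit construction is a defined, reproducible statistic with
the field's sign semantics (positive = exclusive, negative =
co-occurring). It is an interpretation, not a replication of any
particular published z table, whose exact formula is generally not
stated; numerical agreement with externally printed z values is therefore
not claimed.

## Subgroup classification

Both schemes are ordered rule lists (first match wins) over the binary
profile, so every patient receives exactly one label and the firing rule
is recorded:

| precedence | five-way scheme | PanNEN scheme |
|---|---|---|
| 1 | TP53 ∨ KRAS ∨ SMAD4 → TP53/KRAS/SMAD4-Mutant | MEN1 ∧ (ATRX ∨ DAXX) → PanNEN2 |
| 2 | MEN1 ∧ (ATRX ∨ DAXX) → ADM-Mutant | MEN1 → PanNEN1 |
| 3 | ATRX ∨ DAXX → ATRX/DAXX-Mutant | ATRX ∨ DAXX → PanNEN4 |
| 4 | MEN1 → MEN1-Mutant | else PanNEN3/PanNEN5 |
| 5 | else ADM-WT | |

Checking the conjunctive rule before the single-gene rules is required
for the classes to partition the profile space ({MEN1, ATRX} must be
PanNEN2, never PanNEN1). On TP53/KRAS/SMAD4-wildtype profiles the two
schemes correspond exactly (ADM-Mutant ↔ PanNEN2, ATRX/DAXX-Mutant ↔
PanNEN4, MEN1-Mutant ↔ PanNEN1, ADM-WT ↔ PanNEN3/PanNEN5); this is
property-tested over random profiles. PanNEN3 and PanNEN5 are pooled
because no defining somatic signature separates them. The rule tables
ship as editable YAML so users with richer signature definitions (e.g.
additional genes per signature) can override them without code changes.

## Metastasis regression

Outcome: 1 = metastatic lesion. Covariates: indicator columns for genes
mutated in ≥ 5% of primaries or metastases, ordered by descending pooled
frequency (alphabetical tie-break). Clinical covariates (grade, stage,
differentiation) are not in the default design — they are too incomplete
in aggregated cohorts to condition on — but extra columns can be appended
to the design before fitting.

Covariate removal is two-stage and fully deterministic:

1. **Aliased columns** (exactly linearly determined by earlier retained
   columns; R² ≥ 1 − 1e-10, which covers both perfect positive and perfect
   negative correlation, and constant columns) are dropped keeping the
   earlier — i.e. more frequent — column.
2. **VIF pruning**: VIF_j = 1/(1 − R²_j) with R²_j from an OLS regression
   of column j on the remaining covariates plus intercept; the largest
   VIF is removed (alphabetical tie-break) and the loop repeats until all
   VIF ≤ 4. The surviving design's maximum VIF is re-verified on every
   fit as an internal contract.

The MLE is a Newton (IRLS) logistic fit — convergence when the
coefficient update falls below 1e-8, at most 25 iterations — with a BFGS
fallback when perfect separation makes the Hessian singular. Wald
statistics (β/se)² are referred to χ²₁; BH correction is applied across
the gene covariates (not the intercept). 95% CIs are β ± 1.96·se
exponentiated. Non-convergence or any |β| > 10 sets a separation flag on
the results object rather than raising, so screens over many designs can
proceed and filter flagged fits.

## Survival

Kaplan–Meier product-limit estimation (via lifelines) with the standard
tie convention: subjects censored at an event time are still at risk at
that time. The median is the smallest event time with S(t) ≤ 0.5 and is
undefined when the curve never reaches 0.5 — common in indolent disease.
Status coding: deceased → event, living → censored, unknown status or
missing time → excluded with a logged count. The k-group log-rank test
uses the hypergeometric variance at each distinct event time, df = k − 1;
empty groups are dropped with a warning. Greenwood confidence bands are
not part of the headline output. No inter-study stratification is
applied: the pooled curves inherit whatever follow-up heterogeneity the
contributing studies carry, which is a stated limitation rather than a
modelling choice.

## Synthetic cohorts

The generator emulates exactly the structure the pipeline consumes:

- **Marginals.** Per-gene, per-stratum Bernoulli frequencies. The default
  configuration uses the aggregated-cohort headline values — MEN1
  0.419/0.419, TP53 0.055/0.194, KRAS 0.02/0.081, ARID1A 0.02/0.089,
  PTEN 0.065/0.056, FAT1 0.02/0.065, ATM 0.02/0.056 — with 0.02 as the
  fallback for unreported cells. ATRX (0.15/0.10) and DAXX (0.15/0.20)
  are set inside the 10–20% range typical of this disease, with DAXX
  enriched in metastases.
- **Dependence.** Selected gene couples are drawn jointly from the 2×2
  distribution whose marginals are as configured and whose odds ratio ψ
  is the requested coupling; the joint cell solves the Plackett quadratic
  (ψ−1)x² − [1+(pₐ+p_b)(ψ−1)]x + ψpₐp_b = 0 on the Fréchet interval.
  Defaults: ATRX/DAXX strongly exclusive (ψ = 0.05), KRAS/TP53
  co-occurring (ψ = 8). Dependence is pairwise only — a gene may sit in
  at most one couple and no higher-order structure is modelled — which
  is sufficient for the pipeline's pairwise statistics and is a stated
  limitation.
- **Records.** Each mutated gene becomes one MAF-style row with a variant
  class drawn uniformly from the nonsynonymous set. 10% of patients gain
  a second sample carrying a thinned (p = 0.5) subset of their variants,
  exercising representative-sample selection; 5% are labelled grade G3,
  exercising eligibility exclusion.
- **Survival.** Event times are exponential with a per-subgroup rate
  (five-way scheme of the patient's true profile; defaults 0.004–0.014
  per month), censoring is independent exponential at 0.03/month, and
  15% of patients have survival withheld as unknown. With these rates
  roughly a quarter of patients are deceased, matching the deceased
  share of aggregated registry cohorts; exponential forms were chosen
  for their closed-form sanity checks, not biological realism.
- **Determinism.** One `numpy` Generator seeded from the config; the same
  seed yields byte-identical output files.

What passing synthetic tests show: the pipeline recovers known marginals,
detects injected pairwise dependence with the right sign, flags an
injected metastasis association, and is internally consistent end to end.
What they do not show: robustness to study batch effects, panel
heterogeneity beyond the intersection step, variant-calling noise,
mis-annotated histology, or non-exponential survival — none of which the
generator emulates.

## Verification sizes and numerical choices

The test suite checks the Fisher implementation against exhaustive
hypergeometric enumeration on all 2×2 tables with n ≤ 30 (a ≤ comparison
with 1e-12 relative slack absorbs floating error), logistic fits against
closed-form 2×2 odds ratios on 100 random tables, VIF pruning against an
independently recomputed maximum on 100 random collinear designs, and KM /
log-rank against hand-computed product-limit and O−E/V examples.
Stochastic recovery runs use 50 replicates of the default 2000/1000
cohort, with marginal recovery assessed against the 95% binomial CI at
the pooled sample size (a per-replicate CI check would fail ~5% of
replicates by construction). These sizes keep the full suite under a
minute of statistical computation while leaving the binomial half-widths
(≈ ±0.3% for MEN1 at the pooled n) tight enough to catch calibration
errors.

Other numerical conventions: percentages are printed at one decimal place
while machine outputs keep full precision; result tables are written as
UTF-8 TSV with 12-significant-digit reals, making write/read round trips
lossless at that precision; all randomness flows through explicit seeds,
and the analysis path itself contains no random draws.

## Known limitations

- Gene symbols are normalized by uppercasing/stripping only; no HGNC
  alias resolution is performed (a user-supplied alias table hook exists
  but ships empty), so cross-study symbol drift must be handled upstream.
- The carcinoma exclusion is a substring rule over free-text histology
  fields; unusual phrasings can evade it.
- The signed z is a transformation of the Fisher p and inherits its
  discreteness at small counts.
- Percent-scale agreement between schemes' published distributions and a
  reconstruction depends on the exact signature tables; the shipped rules
  cover the six signature genes and are overridable.
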