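# pnetcohort

Aggregated somatic-mutation cohort analysis for well-differentiated
pancreatic neuroendocrine tumors (PNETs).

PNETs are rare and molecularly heterogeneous, so single-institution series
disagree about even basic quantities such as the *MEN1* mutation frequency.
`pnetcohort` is built for researchers who pool targeted-sequencing studies
(e.g. cBioPortal-style MAF and clinical tables) into one analysis cohort and
ask: which genes are recurrently mutated in primary versus metastatic
lesions, which gene pairs are mutually exclusive or co-occurring, how do
tumors fall into molecular subgroups, which mutations are associated with
metastasis, and do subgroups differ in overall survival?

## What it computes

- **Harmonization** — intersect the studies' gene panels, keep
  nonsynonymous variants only, exclude carcinoma/G3 patients, pick one
  representative sample per patient (highest nonsynonymous TMB,
  deterministic tie-break), and emit a binary patient × gene matrix with a
  primary/metastasis stratum per patient.
- **Penetrance** — per-gene frequencies `f = n_mut / n_total` by stratum,
  the ≥ 5% penetrance rule, Pearson χ² or Fisher exact stratum comparisons
  (Fisher whenever an expected cell is < 5), Benjamini–Hochberg FDR.
- **Exclusivity / co-occurrence** — for each penetrant gene pair, a 2×2
  co-mutation table, Fisher two-sided *p*, odds ratio (Haldane–Anscombe
  +0.5 on zero cells), and a signed statistic
  `z = s · Φ⁻¹(1 − p/2)` with `s = +1` when the observed co-mutant count is
  below its independence expectation (exclusivity) and `s = −1` otherwise
  (co-occurrence).
- **Subgroups** — rule-based classification under the PanNEN scheme of
  Ciobanu et al. (PanNEN2 ⊃ PanNEN1 ⊃ PanNEN4 ⊃ PanNEN3/PanNEN5 residual)
  and a five-way scheme in which *TP53*/*KRAS*/*SMAD4* mutations take
  precedence over the *ATRX*/*DAXX*/*MEN1* ("ADM") logic.
- **Metastasis regression** — logistic regression of metastatic status on
  gene indicators (genes mutated in ≥ 5% of primaries *or* metastases),
  with two-stage covariate removal: aliased covariates first, then
  recursive removal of the highest-VIF covariate until all VIF ≤ 4; Wald
  tests with BH correction; odds ratios with 95% CIs.
- **Survival** — Kaplan–Meier product-limit curves per subgroup, median
  survival (first event time with S(t) ≤ 0.5), k-group log-rank test.
- **Synthetic cohorts** — a generator with configurable per-stratum gene
  marginals, pairwise odds-ratio couples (Plackett construction), and
  subgroup-linked exponential survival, so the whole pipeline is testable
  without access to patient data.

## Worked example

Generate a synthetic cohort (600 primaries / 300 metastases), harmonize it,
and fit the metastasis model:

```python
from pnetcohort import harmonize as hz, met_regression as mr, penetrance as pt
from pnetcohort.io_tables import GenePanel, mutations_from_frame, clinical_from_frames
from pnetcohort.synthetic import default_config, generate_cohort

config = default_config(seed=1)
config.n_primary, config.n_metastasis = 600, 300
cohort = generate_cohort(config)

muts = mutations_from_frame(cohort.mutations)
clin = clinical_from_frames(cohort.patients, cohort.samples)
eligible, excluded = hz.apply_eligibility(clin)
panel = GenePanel("synthetic", frozenset(cohort.truth["gene_marginals"]))
matrix = hz.build_cohort_matrix(muts, eligible, panel, assume_sequenced=True)

freq = pt.gene_frequencies(matrix).set_index(["gene", "stratum"])
res = mr.MetastasisLogit.from_cohort(matrix).fit()
print(res.summary())
```

This prints (abridged):

```
cohort: 842 patients; 567 primary / 275 metastatic
MEN1: primary 40.7%  metastasis 40.7%
TP53: primary 5.1%  metastasis 17.8%

Metastasis logistic regression (gene indicators)
  n = 842, log-likelihood = -486.7797
  converged: True in 6 iterations
  aliased removed: none
  VIF removed: none

covariate     beta     se  wald_statistic   p_value   q_value  odds_ratio ...
     MEN1 -0.05403 0.1591          0.1154    0.7341    0.7341      0.9474
     TP53    1.304 0.2602           25.12 5.394e-07 5.394e-06       3.685
```

Reading it: 58 of the 900 generated patients were excluded as grade G3, the
cohort drops to 842; *MEN1* is mutated at ~41% in both strata (its
generating frequency is 41.9%), and *TP53* — generated at 5.5% in primaries
and 19.4% in metastases — comes out with an adjusted odds ratio of 3.7 for
metastasis at q ≈ 5×10⁻⁶, while *MEN1* is null, as designed.

The same analysis is available from the shell:

```bash
pnetcohort simulate --seed 1 --out synth/
pnetcohort run-all --mutations synth/mutations.tsv \
    --clinical-patient synth/clinical_patient.tsv \
    --clinical-sample synth/clinical_sample.tsv --out results/
```

`results/` then holds the cohort matrix, frequency and pair tables,
subgroup assignments and distributions for both schemes, the regression
table with its removal log, per-subgroup survival curves, and a
`manifest.json` recording input digests, every stage's counts, and every
setting in effect.

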