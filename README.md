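# bcpgenomics

Comparative tumor genomics of **breast cancer diagnosed during pregnancy
(BCP)** versus matched non-pregnant controls, packaged as a reusable,
fully tested analysis pipeline with a synthetic-cohort generator.

Case–control genomic studies of BCP ask whether pregnancy reshapes tumor
biology: do cases carry more protein-altering mutations, are particular gene
families (the mucins, whose O-glycosylation uses serine/threonine acceptor
sites) preferentially hit, does a mismatch-repair-deficiency mutational
signature appear in a subset of cases, and do cases fare worse after
adjustment for clinical covariates?  This package implements every analysis
layer needed to answer those questions from standard tabular inputs
(MAF-like mutation tables, SEG copy-number segments, probe-level log2
ratios, an expression matrix, a clinical/survival table), and ships a
generator that produces complete synthetic cohorts with a known ground
truth, so the whole pipeline is testable end to end without any
controlled-access data.

## What it computes

- **Mutation burden** — per-sample SNV/indel counts, non-silent
  classification (missense, nonsense, splice, frameshift, in-frame indel),
  group comparison by Mann–Whitney *U* plus a covariate-adjusted
  nested-model test (age, year of diagnosis, stage, IHC subtype); the ≥5%
  co-mutation frequency table.
- **Intra-tumor heterogeneity** — MATH = MAD(VAFs)/median(VAFs) over all
  mutations with a variant allele fraction.
- **Mucin-family analysis** — carrier status with optional exclusion of the
  artifact-prone MUC4/MUC16, protein-level hotspot detection, serine-gain
  classification of missense changes, and two Monte-Carlo enrichment tests
  (serine gains against a spectrum-conditioned placement null; overlap with
  a known-variant catalog against a uniform placement null), with the
  (1+k)/(1+N) empirical p estimator.
- **Mutational signatures** — 96-channel trinucleotide spectra in the
  pyrimidine-strand convention, non-negative least-squares refitting
  against a bundled reference matrix with a 6% discard–renormalise cutoff,
  presence calls, and the Signature_20 (MMR-deficiency) association suite
  (Spearman ρ with SNV load, MSH2 expression by presence, Fisher test of
  MSH2 deletion, BH-FDR).
- **Copy-number QC and summaries** — MAPD and median lag-1 autocorrelation
  with the 0.30/0.5 array-QC gates and the CCF ≥ 30% filter; fraction of
  genome altered; arm-level gain/loss frequency comparison; length-weighted
  gene-level deletion calls (MSH2).
- **Survival** — Kaplan–Meier curves and medians, log-rank tests, and
  multivariable Cox models (Efron ties) reporting HR with 95% CI.

The statistical conventions live in one module (`bcpgenomics.stats`):
two-sided tests, exact Mann–Whitney enumeration for combined n ≤ 12
without ties, R-convention two-sided Fisher, Benjamini–Hochberg FDR.

## Worked example

Simulate a cohort at the study's size (35 cases, 18 controls) and run the
headline analyses:

```python
import numpy as np
from bcpgenomics import (
    CohortParams, simulate_cohort, burden_comparison, carrier_status,
    mucin_family, mucsig, mann_whitney, survival_analysis,
    refit_exposures, load_reference_signatures,
)

cohort = simulate_cohort(CohortParams(n_bcp=35, n_control=18, seed=7))
groups = cohort.truth["group"]

res = burden_comparison(cohort.catalogs, cohort.clinical, "n_nonsilent")
carriers = carrier_status(cohort.catalogs, mucin_family(), exclude={"MUC4", "MUC16"})
ref = load_reference_signatures()
sig20 = {pid: refit_exposures(spec, ref).proportion("Signature_20") > 0
         for pid, spec in cohort.spectra.items()}
scores = mucsig(cohort.expression, mucin_family())
fit = survival_analysis(cohort.clinical_frame(), "dfs")
```

which prints, with the formatting of the example script:

```
non-silent burden: BCP median 19 vs control 11.0 (MW p = 0.013, adjusted p = 0.076)
mucin carriers (excl. MUC4/MUC16): 34.3% of BCP vs 11.1% of controls
Signature_20 called present in 25.7% of BCP tumors
MUCsig: BCP mean +0.50 vs control -0.97 (MW p = 0.0000)
DFS: log-rank p = 0.563; adjusted Cox HR = 1.55 (95% CI 0.51-4.72)
```

Read this the way you would a small real cohort: the case group shows the
higher non-silent burden (19 vs 11, nominally significant), a three-fold
mucin-carrier excess, an MMR-deficiency signature in a quarter of cases and
a clearly higher mucin metagene; at n = 53 the survival contrast is
directionally right (HR 1.55) but not significant — the population values
the generator encodes (HR 1.81, carrier prevalence 45.7% vs 11.1%) emerge
sharply only at larger cohort sizes, as the test suite verifies.

The same run is available from the shell:

```bash
bcpgenomics simulate --seed 7 --n-bcp 35 --n-control 18 --out-dir cohort/
bcpgenomics pipeline run --config run.yaml   # all stages, one summary JSON
```

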