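# sctarget

Integrative single-cell expression + 3D-genome analysis for prioritizing
metastasis-associated target genes in carcinomas, with a synthetic-data
module that plants known ground truth so every stage is testable end to end.

## The problem

Tumors mix malignant cells with stromal and immune cells, and the malignant
compartment is itself heterogeneous: subpopulations run distinct expression
programs (hypoxia, cell cycle, epithelial differentiation, metastasis-like
states). Finding a gene worth targeting means (i) separating malignant from
non-malignant cells without genotype data, (ii) summarizing intratumoral
heterogeneity into recurrent programs, (iii) funneling program genes through
differential-expression and survival filters, and (iv) asking whether the
surviving candidate's locus also changes at the chromatin-architecture level
between normal and tumor cells. `sctarget` implements that whole funnel as a
tested library.

## Methods at the core

- **CNV-based malignancy calling** (`sctarget.cnv`). Per-cell relative
  copy-number profiles from log-normalized expression: gene-wise centering on
  a reference-cell mean, clipping to ±3, a 101-gene moving average along each
  chromosome, per-cell median re-centering, and subtraction of the mean
  reference profile. A cell is malignant iff its CNV signal
  (mean x̄² over genes) > 0.05 **and** its Pearson correlation with a tumor
  consensus profile (mean profile of the top 5% cells by signal, per sample)
  > 0.5.
- **NMF meta-programs** (`sctarget.programs`). Per malignant cluster,
  non-negative matrix factorization (multiplicative updates, Frobenius loss,
  best of *n* restarts) of variance-scaled relative expression; factor
  loading vectors from all clusters are hierarchically clustered (average
  linkage, distance 1 − Pearson r, tree cut at r = 0.2); each consensus
  cluster's top-20 genes by mean loading form its meta-signature, annotated
  by hypergeometric over-representation against reference gene sets.
- **Target funnel** (`sctarget.targets`). Candidates = DEGs ∩ program
  signature genes; per candidate on a cohort: median dichotomization,
  Kaplan–Meier/log-rank, univariate Cox (Newton–Raphson, Breslow ties); a
  gene passes iff HR > 1, log-rank p < 0.05, and tumor-vs-normal log₂FC > 0.
- **Chromatin structure** (`sctarget.hic`). ICE matrix balancing; A/B
  compartments from the leading eigenvector of the O/E correlation matrix at
  500-kb resolution, oriented so the gene-denser compartment is A;
  insulation-score TADs at 40-kb resolution (480-kb window), with sub-200-kb
  and telomere/centromere domains filtered and cross-condition TADs matched
  at 70% reciprocal overlap; per-locus compartment-switch labels (e.g.
  B→A) and new-boundary flags.
- **Clinical statistics** (`sctarget.clinstats`). Two-sided Fisher exact
  test by hypergeometric point-probability summation, plain Pearson
  chi-square (Fisher chosen automatically when an expected count < 5), the
  IHC H-score (0·neg% + 1·low% + 2·pos% + 3·high%, range 0–300), and ROC
  AUC with the Youden-J cutoff.

## Worked example

```python
from sctarget.pipeline import run_demo
summary = run_demo(seed=1)
```

prints (via `sctarget run-all --outdir out --seed 1`):

```json
{
  "seed": 1,
  "n_cells": 1200,
  "n_called_malignant": 798,
  "malignancy_balanced_accuracy": 0.99875,
  "n_meta_programs_multi_member": 4,
  "n_planted_programs": 4,
  "metastasis_program_found": true,
  "n_candidates": 7,
  "planted_target": "G00281",
  "passing_targets": ["G00281"],
  "locus_compartment_switch": "B->A",
  "n_tads_normal": 6,
  "n_tads_tumor": 5,
  "n_conserved_tads": 4
}
```

Reading this: the simulator planted chromosome-arm CNVs in 800 malignant
cells across 4 samples — the classifier recovers the malignant/non-malignant
split at 99.9% balanced accuracy (798 cells called malignant). Four
co-expression programs were planted; consensus NMF finds exactly four
recurrent meta-programs, two of which annotate as metastasis programs. Of
the 7 candidate genes surviving the DEG ∩ program intersection, the survival
filter passes exactly the one gene planted with hazard ratio 2 and tumor
up-regulation. In the paired contact maps, the locus planted to flip
compartment is called B→A, and the extra tumor TAD boundary splits one
domain (6 vs 5 retained TADs, 4 conserved at 70% reciprocal overlap).

## Command line

`sctarget` exposes thin subcommands over the library: `simulate`, `qc`,
`cnv`, `programs`, `targets`, `hic`, `clinstats`, `run-all`. Each writes a
`run_manifest.json` with its parameters and the package version.

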