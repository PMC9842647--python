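# Methods

This note documents the models, parameter choices and numerical conventions
behind `sctarget`, and what the synthetic-data tests do and do not establish
about real data.

## Single-cell QC, normalization and markers

Cells are kept when 200 ≤ detected genes ≤ 5000 ("detected" = count > 0) and
the mitochondrial count fraction, computed on raw counts, is ≤ 0.30. QC is
idempotent. Normalization scales each cell to a common total (default
10,000) and applies log₂(x+1), so zeros stay zero and proportional cells
become identical.

Marker/DEG statistics are per-gene two-sided Wilcoxon rank-sum tests of one
group against the rest, using the normal approximation with tie and
continuity corrections. At very small group sizes (4 vs 4) the corrected
approximation stays within ~10% of the exact permutation p-value; for
smaller groups an exact test would be preferable, which is why the
preconditions require ≥ 2 cells per group and the tests exercise n ≥ 4.
Benjamini–Hochberg adjustment is applied within each group's gene list
(the adjustment method is a field default, chosen here explicitly). Fold
changes are log₂((mean_in + ε)/(mean_out + ε)) with ε = 1e−9; constant genes
get p = 1 and log FC = 0.

## CNV profiles and malignancy calling

Profiles are computed from log-normalized expression in five ordered steps:
(1) center each gene on the reference-cell mean; (2) clip to ±3; (3) within
each chromosome, average over a symmetric 101-gene moving window (truncated
at chromosome ends; genes ordered by start coordinate — input gene order is
irrelevant); (4) re-center each cell on its median (making profiles
invariant to per-cell additive shifts); (5) subtract the mean reference
profile. Window 101 and clip 3.0 follow the moving-average convention of
expression-based CNV inference; chromosomes with fewer than window/4
annotated genes are averaged over what is available, with a warning. Genes
lacking annotation are dropped from profiles (warned below 80% coverage) but
retained for all expression analyses.

The **CNV signal** is the mean of squared profile values; a max−min "range"
statistic is available behind `statistic="range"` because the phrase "range
of CNV signals" admits both readings — mean-of-squares matches the scale of
the 0.05 threshold and is the default. The **CNV correlation** is the
Pearson r between a cell's profile and a consensus profile; the consensus is
the mean profile of the top 5% of cells by CNV signal, computed within each
sample of origin (the comparator is not fixed by convention; it is
configurable). A constant vector on either side yields r = 0. A cell is
called malignant iff signal > 0.05 **and** correlation > 0.5, both strict;
equality at a threshold is non-malignant.

Reference cells: any non-malignant population works (the pipeline demo uses
all cells not flagged malignant by the generator; the CLI uses a named cell
type). References receive profiles too and score near zero against
themselves.

Gene-set scores (epithelial panel — EPCAM, cytokeratins, SFN — exhaustion
panels, meta-signatures) are the per-cell mean of log-normalized expression
over the present set members; absent members are dropped with a warning and
an empty overlap is an error.

## Expression programs and consensus

NMF input is **variance-scaled relative expression**: within each malignant
cluster, (x − gene mean)/gene SD with negatives clipped to zero. Plain
log-normalized input makes every factor absorb the shared expression
baseline, so factors from different clusters correlate trivially; centering
removes the baseline and the SD scaling flattens the residual noise floor so
it cannot recur across clusters as a spurious "program".

Factorization is multiplicative-update NMF (Frobenius loss, tol 1e−6,
max 800 iterations), best of `n_restarts` (default 10; the bundled pipeline
uses 4) random initializations by reconstruction error, deterministic given
the seed. Factors are L2-normalized with scale absorbed into cell usages so
loading vectors are comparable across clusters. The per-cluster rank k is a
free parameter; the bundled pipeline uses k = 8 (planted-program count plus
headroom for noise factors). On real data a sweep over k ∈ {4..10} with a
factor-stability criterion (mean pairwise r > 0.7 across restarts) is the
recommended procedure; signature counts are parameter-bound, not invariants.

Consensus: all loading vectors are aligned on the union gene universe
(absent loadings = 0), hierarchically clustered with distance 1 − Pearson r
(average linkage) and the tree is cut at distance 1 − 0.2, i.e. a global
correlation threshold of 0.2 across all genes. Meta-programs with ≥ 2
members are the recurrent programs; each one's meta-signature is its top 20
genes by mean loading, ties broken lexicographically, so output is a
deterministic function of the tree cut and invariant to cluster input order.
Annotation assigns the reference set with the smallest hypergeometric
over-representation p, only when its Bonferroni-adjusted p (across sets)
is < 0.01; otherwise "unassigned".

## Target prioritization

Candidates are the exact, case-sensitive intersection of a DEG list with the
top program genes. A generic DEG predicate (adjusted p < 0.01,
|log₂FC| > 1) is provided for bulk-style input lists; the differential fit
that produces such tables is out of scope.

Per candidate: expression is dichotomized at the median (ties to "low" —
the split side for ties is a convention and is documented as such),
then the high/low groups are compared by the product-limit (Kaplan–Meier)
estimator, the 1-df log-rank test over pooled event times, and a univariate
Cox fit. The Cox solver is Newton–Raphson on the partial likelihood with
**Breslow** tie handling (convergence |Δβ| < 1e−8 or 50 iterations; Wald 95%
CI from observed information). Breslow was chosen over Efron because the
simulated survival times are continuous and tie-free, where the two
coincide; on heavily tied real data Efron is less biased. Complete
separation is detected (|β| > 50 or non-finite information) and flagged with
an infinite CI bound rather than raised. A candidate passes iff it is in
both input lists, HR > 1, log-rank p < 0.05 and tumor-vs-normal log FC > 0;
output is sorted by log-rank p. Both the log-rank and the Cox Wald p are
reported, since either may be quoted for a cohort.

## Hi-C structure

All analysis is cis-only on dense per-chromosome matrices.

**ICE balancing**: bins with zero marginal are masked, plus bins below the
2% quantile of the marginal distribution (the quantile is taken over all
bins, so re-balancing an already-balanced map — where previously masked bins
sit at zero — is a no-op; this gives idempotence to 1e−6). Rows/columns are
scaled iteratively until the coefficient of variation of retained marginals
falls below 1e−5 (max 200 iterations; non-convergence is flagged, not
raised). One balancing scheme is used throughout; regression-based
normalization schemes exist but a single balancer suffices for compartment
and TAD calling.

**O/E**: each entry is divided by its diagonal (distance) mean within the
chromosome, so every retained diagonal averages 1.

**Compartments** (500-kb bins): leading eigenvector (largest |eigenvalue|)
of the Pearson correlation matrix of O/E columns, per chromosome — the
standard construction. The sign is oriented so that the mean gene density
(count of annotated gene starts per bin) of positive bins is at least that
of negative bins; positive = A. Exactly equal densities fall back to
"larger block = A" with a warning. Masked (low-coverage) bins carry no call:
they are NA, not B. A locus's compartment status is the majority sign over
its overlapping bins, ties labelled "ambiguous"; switch labels concatenate
the two conditions' statuses (e.g. "B->A").

**Insulation and TADs** (40-kb bins): the insulation score at bin i is
log₂ of the mean balanced contact in the square [i−w..i−1]×[i+1..i+w]
(w = window/resolution) over the chromosome mean of that quantity — a ratio
statistic, invariant to global scaling, NA within one window of chromosome
ends. The window is 480 kb (12 bins): near the original ~500-kb convention
while divisible by the bin size. Boundaries are downward zero crossings of
the delta vector (mean IS left-of minus right-of over a 100-kb delta window)
whose peak-to-trough depth is ≥ 0.1 (unstated upstream; configurable); the
boundary bin is the IS minimum around the crossing, which can land on either
bin flanking the planted edge — recovery is therefore stated to ±1 bin.
TADs are the intervals between consecutive boundaries. Domains shorter than
200 kb, or overlapping a supplied excluded-region BED (telomeres/
centromeres; coordinates are input, not built in), are flagged filtered with
the reason but kept in the output. Cross-condition TADs are conserved iff
the overlap is ≥ 70% of **both** lengths (reciprocal; ≥, so an exact 0.70
fraction qualifies), each TAD matching at most one partner (greatest
overlap, ties to leftmost). The per-gene structure report combines
compartment status per condition, the switch label, a boundary-change flag
(a retained boundary within 2 bins of the gene in exactly one condition) and
the insulation difference at the gene's bin.

## Clinical statistics

Fisher's exact test is two-sided by point-probability summation: with
margins fixed, all tables whose hypergeometric point probability is ≤ the
observed one (relative slack 1e−7) contribute — the common software
convention. The chi-square test is plain Pearson (1 df) with no Yates
correction by default; Yates is available behind a flag. On the two bundled
cohort tables, these conventions reproduce the printed p-values to 4
decimal places for age, gender, grade, stage (both cohorts) and 5-year
overall survival (small cohort). Two printed rows are **not** reproduced by
either convention — the small cohort's 5-year recurrence row (printed
0.2075; two-sided Fisher gives 0.1975) and the large cohort's overall
survival row (printed 0.0003; plain chi-square gives ~0.0002) — the test
used for those rows is evidently different or the counts were rounded; they
are excluded from the reproduction suite. `cohort_table` selects Fisher
when any expected count is < 5 and chi-square otherwise, which matches the
apparent convention of the published tables (Fisher at n = 29, chi-square at
n = 293).

The H-score is 0·negative% + 1·low-positive% + 2·positive% +
3·high-positive% over four staining classes summing to 100 (±0.01),
linear in the fractions with range [0, 300], the extremes attained only at
the pure-class corners. ROC AUC is the rank (Mann–Whitney) statistic with
midrank tie handling, identical to concordant-pair counting; the cutoff
maximizes Youden's J over midpoints between adjacent distinct scores, ties
resolved to the lowest cutoff, with "positive" meaning score > cutoff.

## Synthetic data: what it emulates and what it does not

The single-cell generator draws per-gene baseline means from a log-normal,
gamma library-size factors per cell, and composes multiplicative effects —
chromosome-arm CNV dosage (2^log₂dosage on malignant-cell means, applied
before noise), jointly up-shifted program gene sets in randomly chosen
active malignant cells, and optional cell-type marker shifts — then applies
gamma-Poisson (negative binomial, dispersion 0.15) noise and Bernoulli
dropout (rate 0.2). Defaults for the bundled study conditions: 4 samples ×
(200 malignant + 100 non-malignant) cells, 2,000 genes over 10 chromosomes,
three planted arms at |log₂ dosage| ∈ {0.5, 1} covering ~30% of the genome,
four 30-gene programs at log₂ effect 2 active in 240–300 cells.

The Hi-C generator builds expected contacts as depth × (d+1)^−decay with a
within-TAD enrichment factor (default 2) and a rank-1 compartment
modulation 1 + strength·s_i·s_j (default strength 0.3–0.4), then applies
multiplicative log-normal noise, symmetrized. Survival tables are
exponential event times with a group hazard ratio and independent
exponential censoring.

Not emulated: doublets, ambient RNA, batch effects, gene-length effects,
UMI saturation; Hi-C trans contacts, fragment-level biases, copy-number
effects on coverage; non-proportional hazards or informative censoring.
Passing tests therefore demonstrate the pipeline's correctness and its
recovery power under these idealized noise models, not performance on real
tissue, where reference-cell contamination, subclonality and batch structure
add failure modes the generator does not create.

## Problem sizes and calibration of the test suite

The suite simulates at desk scale: malignancy calling and meta-program
recovery run on the 1,200-cell default dataset (the consensus recovery
property is checked over 20 seeds); compartment recovery uses 100-bin maps
at noise SD 0.3 over 20 seeds; TAD recovery uses 100-bin maps over 20 seeds
with boundaries placed inside the insulation-defined interior; log-rank null
calibration uses 500 replicates at 30/group; Cox hazard-ratio recovery uses
100 seeds at 500/group with light (rate 0.02) censoring, so that the cohort
carries enough events for the estimator's sampling spread to sit inside the
stated [1.7, 2.3] recovery band. Exact tests (Fisher, hypergeometric
enrichment, AUC) are verified against brute-force enumeration on small
instances, ICE against an independent Sinkhorn iteration, and KM/log-rank/
Cox against hand-computed product-limit examples, a grid-search maximizer of
an independently coded partial likelihood, and an established survival
library.

## Known limitations

- The CNV smoother assumes enough genes per chromosome (~window/4) and a
  reference population free of large CNVs; tumor-contaminated references
  shrink signal toward zero.
- Mean-of-squares CNV signal conflates many small deviations with few large
  ones; the range statistic is offered but shares the ambiguity.
- The NMF k and the 0.2 consensus threshold control how many meta-programs
  emerge; counts should be reported with their parameters.
- Breslow ties, median dichotomization and the no-Yates chi-square are
  conventions; alternatives change third-decimal p-values on real cohorts.
- Compartment calls at low-coverage bins are NA by design; loci mapping only
  to masked bins get no switch label.
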