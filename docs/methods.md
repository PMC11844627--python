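# Methods

## Model and procedure

### Pathway scores

A MitoPathway score is the unweighted arithmetic mean of the expression of a
pathway's member genes present in the matrix. This is deliberate: the mean
keeps the score in the input unit, makes it linear in per-sample scaling
(scaling a sample by c scales all its scores by c, a property asserted in
the tests), and means a parent pathway's score is the mean over its *genes*,
not the mean of its children's scores — children of unequal size therefore
contribute proportionally to their gene counts. Genes absent from the matrix
are simply left out of the mean; we report a per-pathway coverage fraction
and flag pathways below a configurable threshold (default 0.5) rather than
rescaling or imputing, because a rescaled mean would silently change the
estimand. A pathway with no gene present scores NaN and is listed, never
zero.

### Prioritization scores (mitoPPS)

For sample Si and pathway Pi, with n′ pathways and reference set R of x′
samples:

mitoPPS(Si,Pi) = (1/(n′−1)) Σ_{Pn≠Pi} [ r_Si(Pi,Pn) / mean_{Sx∈R} r_Sx(Pi,Pn) ],
where r_S(Pi,Pn) = Score(S,Pi)/Score(S,Pn).

Two identities follow algebraically and are enforced at tight tolerances:

- **Scale invariance** (≤1e-12): r_S is a within-sample ratio, so any
  per-sample positive factor cancels. This is what makes the score
  insensitive to mitochondrial content and sequencing depth, and what makes
  scores comparable across datasets with similar gene coverage.
- **Mean-1** (≤1e-9): with R = all samples, the mean over Sx of
  r_Sx/mean(r_Sx) is 1 for every pathway pair, so the per-pathway mean of
  mitoPPS is exactly 1. With a control reference the identity holds over
  the control subset instead.

The production implementation materializes the n′ × n′ × x′ ratio tensor and
averages over partner pathways (≈10 MB of doubles at 149 pathways × 55
samples); the test suite holds it to ≤1e-12 agreement with a literal
triple-loop evaluation of the double sum, so the vectorization can never
drift from the definition.

**Nonfinite policy.** A zero or missing pathway score makes some ratios
infinite. The default policy excludes the offending sample and reports it
(with the offending pathways); an `error` policy and an epsilon-floor policy
(floor = smallest positive score × 1e-3) are available, the floor OFF by
default because exclusion keeps the remaining scores exact while flooring
perturbs every ratio involving the floored pathway.

**Cross-dataset integration.** Each dataset's mitoPPS is computed against
its own reference and the results concatenated; no cross-dataset
re-normalization is applied, since the scores are unitless and internally
normalized. We report gene coverage but do not enforce a comparability
cutoff — there is no principled threshold, so the judgment is left to the
analyst.

**Derived quantities.** Prioritization percent is (mitoPPS − 1) × 100;
log10 mitoPPS (0 = average priority) is the heatmap scale; the dynamic
range of a pathway is max − min mitoPPS over a sample set, computed on the
linear scale.

## Normalization and cleaning

**TMM.** Trimmed mean of M-values with the canonical defaults: reference
column = sample whose 75th-percentile count fraction is closest to the mean
75th percentile (ties broken by column order); per pair, genes with a zero
in either column are dropped (no pseudocounts); 30% of M values and 5% of A
values trimmed from each tail; inverse-asymptotic-variance precision
weighting on; factors re-centered to geometric mean 1. Our implementation
matches the Bioconductor reference implementation to ≤1e-4 on a frozen
50-gene × 4-sample fixture with a compositional outlier (the oracle output
was produced once by running that package and frozen into the test).
Normalized values are counts per million on the effective library size
(library size × factor). Only a plain CPM fallback is offered besides TMM.

**Imputation.** For intensity matrices with missingness: genes missing in
all samples are removed first; if the input is log10-transformed it is
exponentiated; each remaining missing cell gets half the gene's minimum
observed value (a low, nonzero detection-limit stand-in). Missingness is
always NaN, never zero, and the operation is idempotent.

**Transforms.** Per-gene z-score (population sd; constant genes map to zero
with a warning), log10 and log2 with an optional pseudocount.

## Multivariate layer

PCA is SVD-based with prcomp-style defaults (center on, scale off); callers
pass pre-transformed matrices (z-scored expression for gene-level maps,
log10 mitoPPS for prioritization maps). Component signs are fixed by making
each loading vector's largest-magnitude element positive so plots are
comparable across runs. Hierarchical clustering is Ward.D2 on Euclidean
distances via scipy's `linkage(method="ward")`, which implements the same
Lance-Williams recursion; a hand-coded naive recursion on a 6-point fixture
is the test oracle. k-means uses 25 seeded restarts. Spearman correlations
use average ranks for ties and the t-approximation for p-values (adequate
at the sample counts involved here).

**Two-group tests.** Gate tests at alpha 0.05 (configurable; the choice of
0.05 is our default, not an empirical calibration): Shapiro-Wilk per group
for normality, Fligner-Killeen for variance homogeneity. Normal +
homogeneous → Student's t; normal + heterogeneous → Welch; non-normal +
homogeneous → Wilcoxon rank-sum; non-normal + heterogeneous →
Brunner-Munzel. All gate p-values are reported so the routing is auditable.
Effect sizes are Hedges' g: pooled-SD Cohen's d × (1 − 3/(4·df − 1)),
df = n_x + n_y − 2. No multiple-testing correction is applied across
pathways — contrasts are reported singly; treat families of contrasts
accordingly (documented limitation).

**Fold differences.** Population-style contrasts default to ratio of group
means; donor-matched designs use mean of per-pair ratios (with per-pair
range). Both are exposed because they answer slightly different questions
and differ under heterogeneity.

## Synthetic data: what it emulates and what it does not

The generator draws expression(g, s) = base(g) · scale(s) ·
priority(group(s), pathway(g)) · LogNormal(0, σ), with an optional Poisson
count mode around that mean (to exercise the TMM path) and an optional
missing-at-random mask (to exercise imputation). Defaults: 300 genes over a
12-pathway 3-level mini-hierarchy (2 top branches → 4 modules → 6 leaves,
genes assigned round-robin to leaves, parents holding the unions — small
enough for the brute-force oracle), 24 samples in 4 groups, σ = 0.1,
per-sample scale factors log-uniform on [0.2, 5] emulating the spread of
mitochondrial content across tissues. Priority factors ≡ 1 is the null
model of proportional expression (no specialization); planted factors
multiply the genes of the chosen pathway in the chosen group.

Noise is multiplicative log-normal because every downstream quantity is
ratio-based; per-sample scale factors are the confound the prioritization
score must cancel, and the tests verify exactly that. What the generator
does **not** emulate: gene-gene correlation within pathways, full
transcriptome backgrounds, overlapping gene membership beyond the
parent/child unions, cell-type mixture effects, or batch structure. Passing
tests therefore demonstrate the estimator's algebraic behavior and its
recovery of planted multiplicative signals — not robustness to correlated
biological noise in real tissue data.

Recovery is summarized by the mean per-sample Spearman correlation between
recovered and noiseless-truth prioritization rankings, plus, for each
planted (group, pathway), whether that pathway tops the group-vs-rest
mitoPPS difference. With most pathways near-tied at priority ~1, the rank
correlation is far below 1 under noise even when detection is perfect; it
reaches exactly 1 at σ = 0.

## Numerical choices and degenerate inputs

- All invariant tolerances as above (1e-12 algebraic, 1e-9 accumulated,
  1e-4 vs the external TMM reference).
- TMM reference ties and k-means both resolve deterministically (column
  order; fixed seed with 25 restarts).
- Symbol matching is exact after alias rewriting (no case folding —
  MitoCarta symbols are uppercase-canonical, and folding could merge
  distinct mouse/human symbols). The alias table ships two rules (restore
  the "MT-" prefix on bare mtDNA gene stems; C12orf10 → MYG1), accepts
  user extensions from TSV, and is validated idempotent at construction.
- Pathway ids are the full hierarchical path string, disambiguating short
  names reused at different levels.
- Degenerate inputs fail loudly: all-zero count columns, empty reference
  sets, single-pathway score matrices, matrices with no mitochondrial genes
  (almost always an identifier-space mismatch), log of nonpositive values
  without a pseudocount.

## Problem sizes

The test suite and the acceptance script run entirely on generated data at
desk scale: 10 × 6 score matrices for oracle equivalence (50 seeds),
300-gene × 40-sample cohorts for planted-signal recovery (100 seeds), a
50 × 4 fixture for TMM. These sizes were chosen so the brute-force oracles
stay exact and fast while exercising every code path; the implementation
itself is vectorized and runs comfortably at atlas scale (149 pathways ×
hundreds of samples).

## Known limitations

- Pathways with few genes yield noisy scores and prioritization estimates;
  the coverage flag mitigates but does not fix this.
- Mean-based scores measure transcriptional program activation, not
  realized flux or functional capacity.
- Bulk tissue mixtures dilute cell-type-specific mitochondrial phenotypes;
  nothing here deconvolves them.
- No multiple-testing correction across pathways (see above).
- The `atlas` command requires the user to download the public input files
  themselves; it only ever reads local paths.
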