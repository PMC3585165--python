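# Methods

This note documents the statistical models, the synthetic-data
generator, the numerical conventions and the genuinely open design
choices in `musclenet`, in the order the pipeline runs them.

## Data model

The central object is a genes × samples matrix of log2-scale,
RMA-normalised expression intensities with unique gene and sample IDs
and finite values, plus a two-group sample annotation.  All I/O is plain
tab-delimited text; GEO series-matrix comment lines (`!…`) are tolerated
on read.  Printed fold changes are stored as *signed linear* FC
(−4.82 means 4.82-fold down) with the convention
log2FC = sign(FC)·log2|FC|.

## Variance filter

A gene is kept when its interquartile range across all samples exceeds
`iqr_min` (default 0.25 log2 units).  Percentiles use linear
interpolation between order statistics (the "type 7" convention); this
matters because the filter count is sensitive to the percentile rule at
small n.  The comparison is strict (`>`); a flag allows `≥`.

## Moderated differential expression

Per gene, an equal-variance two-group contrast (case − control).  The
pooled residual variance $s_g^2$ ($d_g = n_1+n_2-2$ df) receives a
scaled inverse-chi-square prior whose hyperparameters $(d_0, s_0^2)$ are
fitted by moment matching on $e_g = \log s_g^2 - \psi(d_g/2) +
\log(d_g/2)$: the excess of $\mathrm{var}(e_g)$ over $\psi'(d_g/2)$
determines $d_0$ through the inverse trigamma (Newton iteration,
tolerance 1e-12), and the mean of $e_g$ determines $s_0^2$.  When the
observed spread of log variances does not exceed sampling noise the fit
returns $d_0=\infty$ (all genes share $s_0^2$; the reference
distribution becomes normal).  Zero-variance genes are excluded from
the hyperparameter fit but still shrunk, so no posterior variance is
ever zero.  `prior_df=0` disables shrinkage and reproduces the
classical pooled t exactly; the test suite verifies both the closed form
and bit-level agreement with Bioconductor `limma` on a small matrix.
Benjamini–Hochberg adjustment is the standard step-up rule
(min over j ≥ i of m·p(j)/j, capped at 1), implemented directly and
cross-checked against `statsmodels` in tests.

Default cutoffs: |log2FC| ≥ 1 and adjusted p ≤ 0.05, two-sided
throughout.

## Transposed PCA and the discriminant component

The decomposition treats genes as observations and samples as
variables: an SVD of the per-sample mean-centred genes × samples matrix
(covariance PCA; correlation PCA behind a `standardize` flag, and an
uncentred mode is available because the upstream convention is not
fixed).  Gene scores are the projections $US$; factor loadings are the
Pearson correlations between each original sample column and each score
vector, computed by direct recomputation rather than rescaled
eigenvectors so they remain exact under either centering mode.
Components are ordered by decreasing eigenvalue and each is oriented so
its largest-|score| gene is positive — PCA signs are arbitrary and
tests need determinism.  Components with numerically zero variance get
zero loadings.

Because the per-gene baseline (the tissue profile) varies across genes
but is common to all samples, per-sample centering does not remove it
and PC1 absorbs it; group differences surface from PC2 onward.  The
discriminant component maximises the Fisher discriminant ratio
(squared mean difference over pooled within-group variance) of its
factor loadings between the two groups — the exact reduction of a
one-feature linear discriminant analysis.  PC1 is excluded by default
(flag to include); a configurable floor (default 0) flags the selection
as non-discriminating when even the best ratio is below it.  The top-K
(default 100) genes by |score| on that component, ties broken by gene
ID, form the network node set.

Sample QC uses classical scaling (principal coordinates) of the
samples' pairwise Euclidean distances, delegated to scikit-bio's PCoA;
3 dimensions by default.

## Surrogate-calibrated correlation networks

Each group's network is built from that group's samples only (default;
a pooled mode exists because the upstream description is ambiguous on
this point).  Edges connect pairs with Pearson r strictly greater than
τ; an absolute-value rule is available but positive correlation is the
default.  Constant genes yield r recorded as 0 with a flag.

Threshold calibration: for each τ in a grid (default 0.50–0.99, step
0.01) the original connection count is compared with the count in
surrogate data, where every gene's values are independently permuted
across individuals — marginals exactly preserved, inter-gene
correlation destroyed.  The ensemble (default 1000 realizations, each
seeded as `[seed, i]` so runs are bit-reproducible) gives a per-τ mean,
SD and upper quantile.  A grid point qualifies when

* the original count is positive,
* the surrogate mean is at least `margin` (default 10%) below the
  original count, and
* the original count exceeds the ensemble's empirical 0.99-quantile.

The third condition is a robustness guard this package adds: at n = 7
the expected chance edge count near τ = 0.95–0.99 is of order one, so a
single chance edge would otherwise satisfy the 10% margin on completely
independent data about half the time.  Setting
`surrogate_quantile=None` recovers the bare margin rule.

Among qualifying thresholds the **largest** is selected by default.
With a genuine co-expression module in the data the 10% margin is
already met at low τ, where most edges are chance at this sample size;
the largest qualifying τ yields the network least contaminated by
chance connections.  `selection="smallest"` is available.  When no grid
point qualifies the pipeline falls back to a configurable τ (default
0.95) and records the fact in the calibration table and manifest.

Topology statistics: average degree AD = 2C/N, degree sequence,
connected components and isolated-node count, with GraphML and edge-TSV
export.  The two group networks are compared on a shared node set
(AD, edges, isolates, largest component, edge-set difference).

## Over-representation analysis

A generic stand-in for database-backed annotation tools: one-sided
hypergeometric tail per GMT set against a user-supplied background,
optional EASE variant (overlap − 1), BH across tested sets, FDR ≤ 0.05
filter.  Sets with fewer than two background members are reported
untested.  It makes no attempt to reproduce any particular annotation
database's term content.

## Synthetic data generator

`SyntheticConfig` defaults encode the emulated study regime: 8793
genes, two groups of 7, 96 shifted genes at ±1.5 log2 units (signs
random), per-gene baseline SD 2.5 around level 7.0, residual noise SD
0.3, and one 22-gene case-only block targeting pairwise r = 0.97.
Choices where no upstream value exists: the 1.5 log2 shift matches the
median printed fold change (~2.5-fold); baseline SD 2.5 with noise 0.3
puts ~98% of variance on the tissue axis, comfortably above the >97%
regime; noise 0.3 is a typical RMA residual scale.

Blocks are induced by one latent factor per block,
value = √ρ·factor + √(1−ρ)·noise, which gives pairwise correlation ρ in
expectation; block members are independent in the other group.  When
the planted DE set is at least as large as the blocks, block genes are
drawn from inside the DE set, so the co-expressed disease module is
also differentially expressed and therefore enters the discriminant
top-100 — the configuration the pipeline is meant to detect.  The
generator writes its ground truth (shifted genes with signs, block
membership, block group) to a plain text file.

What the generator does *not* emulate: probe-level effects, batch
structure, missing values, heteroskedastic per-gene noise (hence the
fitted prior df is typically infinite on synthetic data, unlike real
arrays), and the pervasive weak biological correlation of real
transcriptomes.  Passing tests therefore demonstrate correctness of the
machinery and its behaviour under the stated regime, not performance on
real arrays; in particular the IQR-filter pass rate and the calibrated
threshold on synthetic data need not match values observed on any real
dataset.

## Problem sizes in the test suite and acceptance script

Tests run the generator at 30–2000 genes and 4–14 samples — the
smallest sizes at which each property is informative — and calibration
with 50–400 surrogate realizations; the acceptance script runs the full
pipeline at the study scale (8793 × 14, 1000 realizations), which
completes in seconds.  Monte-Carlo assertions state their tolerance
inline (binomial 3σ bands, ensemble-SD bands, or relative bounds of
30% where a rate of order 10⁻³ is estimated from ~10⁶ dependent
pairs).

## Known limitations

* The empirical-Bayes fit assumes a common variance prior across all
  genes; no intensity-dependent trend is modelled.
* Only two-group designs; no covariates, pairing or batch terms.
* The discriminant selection is one component at a time; interactions
  between components are not considered.
* Calibration assumes exchangeable individuals within a group;
  structured noise (e.g. batch) would inflate surrogate counts.
* Networks use marginal Pearson correlation; no partial correlations,
  and no topology statistics beyond degree/components/isolates.
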