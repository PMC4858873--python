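# Methods

## Scope and model of the data

The package analyzes a raw count matrix (transcripts × cells, non-negative
integers) from a FACS-sorted single-cell cohort, with one gate label per
cell (X1 = cycling stem cells, X2 = immediate progeny, other).  The
analysis assumes cells sample a continuum of differentiation states, that a
modest set of transcripts carries the state signal (hence variable-gene
selection), and that a one-dimensional path through expression space is a
meaningful summary for any single lineage (branching is handled one lineage
at a time, never as a multi-branch pseudotime).

## Normalization

Size factors are the plain median-of-ratios estimator: the reference set is
every gene with strictly positive counts in all cells; for cell j,
sf_j = median over reference genes of c_gj divided by the gene's geometric
mean across cells.  No post-hoc rescaling is applied, so results are
bit-for-bit reproducible from the definition.  If no gene is detected in
every cell the estimator is undefined and the package raises an error
rather than silently switching estimators.  A subtlety worth recording:
scaling a single cell's column by c multiplies its size factor by c only
*relative to the others* — all factors also pick up a common c^(−1/n)
through the geometric means — so the homogeneity property is exact only up
to that global constant, and the tests assert the exact statement.
Expression is log2(normalized count + 1); zeros map to zero.

## Variable-gene selection

Each gene's normalized counts are upper-Winsorized: the two largest values
(n_winsor = 2 by default) are replaced by the next largest, so a couple of
extreme cells cannot dominate the variability estimate.  The lower tail is
untouched because the procedure exists to stop outliers *inflating*
variance.  Winsorization happens before both the mean and the CV
(unbiased-SD / mean).  A straight OLS line of log2 CV on log2 mean is the
technical-noise trend; genes are ranked by standardized residual
(residual / residual standard error), with ties broken by descending log
mean then gene id so selection is reproducible.  The final set is the top
N ranked genes with log2 mean above a floor (default 3, i.e. mean
normalized count > 8), which removes genes whose apparent variability is
dropout-driven.  The 95% confidence band of the fit is computed for
reporting; selection itself uses only rank + floor.  A gamma-GLM variant of
the trend was deliberately not implemented: the simple line on the log-log
scatter is the procedure this pipeline standardizes.

## Clustering

Cells are observations, the selected genes features, distances Euclidean,
linkage Ward with heights on the distance scale (the ward.D2 convention;
verified in the tests against R's hclust on a frozen configuration to
1e-9).  The dendrogram cut into k groups renumbers clusters by first leaf
appearance.  k is a required parameter with 10 as the documented default
for head-cohort-scale data; the synthetic study uses k = 6 because the
generator has six states.  Merge-cost ties are resolved by the linkage
implementation's deterministic order; ties are measure-zero on continuous
log-expression input, so no bespoke tie-break was layered on top.  The 2-D
t-SNE embedding is deterministic given its seed and is strictly
presentational — no downstream computation reads it.  Group enrichment uses
the standardized Wilcoxon rank-sum statistic (normal approximation with tie
correction) of group versus rest on log expression.

## Trajectory (Waterfall)

PCA is by SVD on gene-centered (unscaled) log expression, with the sign of
each loading column fixed so its largest-magnitude entry is positive.  Two
PCs are used by default — the lineage reasoning in this style of analysis
lives in the PC1/PC2 plane — and the count is a parameter.  k-means
(k-means++ seeding, best of 10 restarts, fixed seed) summarizes the score
cloud; k defaults to 10.  Centers are joined by a Euclidean minimum
spanning tree.  Linearization takes the unique tree path between explicit
endpoints when given, otherwise the weighted diameter path; centers left
off the path produce a structured branching warning, the cue to subset
groups per lineage or pass endpoints.

Orientation compares mean stem-marker log expression of the cells assigned
to the two terminal centers: the stem-high end is the root.  If
differentiation-lineage markers are supplied they must be higher at the far
end; a disagreement keeps the stem decision and emits a conflict warning.
An exact tie raises an error asking for explicit endpoints.

Pseudotime: each cell is projected orthogonally onto the polyline through
the ordered centers; raw pseudotime is arc length from the root to the
projection, clamped at the ends, normalized by total polyline length to
[0, 1].  Two per-cell residuals are stored because they answer different
questions: the orthogonal distance to the polyline (projection quality) and
the distance to the nearest k-means center (the quantity conventionally
plotted on the y axis of pseudotime figures).  Reversing the path maps
t → 1 − t exactly; rigid rotations of the score space leave pseudotime
unchanged.

Whether pseudotime should be normalized to [0, 1] is not fixed by the
procedure's ancestry; normalization was chosen so pseudotimes are
comparable across runs, and the raw arc length is kept alongside.

## Gene trends

Trends over pseudotime use a hand-rolled degree-2 local polynomial
regression: at each of 100 grid points the nearest ceil(span·n) cells
(span default 0.75) are tricube-weighted and a quadratic is fitted; the
fitted value is the local intercept.  The pointwise 95% band is
fit ± t_{0.975,n−3} · σ · ‖l(x)‖, where l(x) is the equivalent-kernel row
of the local fit and σ² is the residual variance of the smoother at the
observed points (n − 3 degrees of freedom).  No installed library provides
a degree-2 local fit with standard errors, hence the in-house
implementation.  Degenerate windows (fewer active points than
coefficients) widen to the nearest three points with uniform weights;
constant input yields a constant curve with a zero-width band that still
covers it.

## Synthetic cohorts

The generator emulates the head stem-cell cohort the pipeline targets:
168 cells by default, 1200 genes, a trunk (early proliferative state →
pluripotent-like state) bifurcating at t = 0.5 into a neural branch
(→ neural-primed stem state) and a differentiation branch (three further
states) that crosses into the X2 gate at t = 0.75.  Cells draw a branch
(50/50), t ~ Uniform(0, 1) — state occupancy is not density-modeled — and
a log-normal library size (σ = 0.3).  Counts are negative binomial via the
gamma–Poisson mixture (per-gene dispersion 0.3–0.4; 0.15 for
housekeeping), then thinned by dropout with probability
expit(1.0 − 1.5·ln(μ+1)): ~40% at mean 1, ~3% at mean 10, negligible at
housekeeping levels.  Marker blocks: 30 declining stem markers and 20
declining cell-cycle markers (both branches), 20 neural markers rising on
the neural branch only, 10 genes peaked at the neural transition, 10
peaked at the differentiation branch's gate crossing, 20 ubiquitous
high-expression housekeeping genes (these anchor the median-of-ratios
reference set, as tubulin-class transcripts do in real cohorts), and flat
background with log-uniform baselines, of which 40% switch off along the
differentiation branch so detected-transcript counts fall late in that
lineage.  Marker midpoints and steepness are drawn once from a fixed
internal stream and spread across pseudotime — real marker cohorts turn
over at staggered times, and this staggering is also what makes position
identifiable along the whole axis.  Branch-specific programs use steep
logistics centered after the branch point, so the branches diverge
slightly before it (mild transcriptional priming) rather than being forced
to exact pre-branch equality.

What the generator does *not* emulate: amplification noise beyond NB
overdispersion, batch effects, cell-cycle structure orthogonal to the
lineage, doublets, or realistic transcriptome size (1200 genes versus tens
of thousands).  Passing the recovery benchmarks therefore shows the
pipeline's logic is sound under its own assumptions at cohort scale, not
that it is robust to every artifact of real data.  One visible
consequence: the correlation between transcripts detected and total reads
is higher in simulation (~0.6–0.7) than in real cohorts, because the
log-normal library size is the only depth process and acts on both
quantities at once.

## Benchmarks and study sizes

The recovery benchmark simulates 168 cells × 1200 genes, selects the top
300 variable genes (a quarter of the transcriptome, matching the 1000-of-
~tens-of-thousands proportion of full-scale data), Ward-cuts at the true
state count (6), keeps clusters whose majority true state lies on the main
lineage — the in-silico counterpart of choosing the stem/neural groups by
marker knowledge — and runs the trajectory with four stem and two neural
markers for orientation.  Scoring uses the neural-branch cells (main
lineage), with 20 cohorts per study; these sizes keep each benchmark in
seconds while leaving the recovery question honest.  Clustering recovery
uses 3–6 spherical populations with centers ~100 standard deviations
apart, where exact recovery (ARI = 1) is the correct expectation.

## Known limitations

- Projection pseudotime inherits k-means granularity: within-segment
  ordering is exact but curvature between centers is linearized.
- Orientation requires at least one informative stem marker; cohorts
  without curated markers must pass explicit endpoints.
- The median-of-ratios estimator needs ubiquitously detected genes; very
  sparse matrices must be pre-filtered or externally normalized.
- `group_enriched_genes` is a rank-sum screen, not an error-model-based
  differential-expression method.
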