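# scwaterfall

Clustering and Waterfall-style pseudotime analysis for single-cell RNA-seq
of planarian stem cells, with a ground-truthed branching-lineage simulator.

Planarian neoblasts — the flatworm's adult stem cells — are the only
proliferating somatic cells in the animal and are isolated by FACS on DNA
content (the X1 gate holds cycling stem cells, the X2 gate immediate
progeny).  Given a raw transcripts × cells count matrix from such a cohort,
this package reconstructs the differentiation structure of the population:

1. **Normalization** — median-of-ratios size factors
   (sf_j = median_g c_gj / (∏_i c_gi)^{1/n} over genes detected in every
   cell), then log2(x + 1).
2. **Highly variable transcripts** — per-gene Winsorized mean and CV,
   OLS regression of log2 CV on log2 mean, genes ranked by standardized
   residual, top N kept above a mean floor (log2 mean > 3).
3. **Cell groups** — Euclidean distance + Ward agglomeration (ward.D2
   heights) over the selected genes, dendrogram cut into k groups; t-SNE
   for display only.
4. **Waterfall trajectory** — PCA (2 PCs), k-means centers, Euclidean
   minimum spanning tree over the centers, linearization to one lineage
   path, orientation by stem/lineage marker expression, and per-cell
   pseudotime as normalized arc length of the orthogonal projection onto
   the center polyline (the stored y axis is each cell's distance to its
   nearest center).
5. **Gene trends** — degree-2 local polynomial regression (tricube
   weights) of expression over pseudotime with a pointwise 95% band.

The `synthetic` module generates cohorts with known truth: a stem trunk
that bifurcates into a neural branch and a differentiation branch crossing
the X1→X2 gate boundary, negative-binomial counts with mean-dependent
dropout, and designated marker blocks (declining stem and cell-cycle
markers, rising neural markers, transition-peaked genes, and background
genes that switch off along the differentiation branch so transcript
detection falls late in that lineage).

## Worked example

```sh
python analysis/01_simulate_cohort.py
python analysis/05_waterfall_main_lineage.py
```

prints (seed 1):

```
simulated 1200 genes x 168 cells (seed 1)
  X1 cells: 150, X2 cells: 18
...
main-lineage clusters: [1, 3, 4]
orientation: root center 2 (stem-marker decision)
mean pseudotime per true state (expected increasing):
group_true
Group2        0.095
Group1        0.167
nuNeoblast    0.751
Spearman rho vs truth on the neural branch: 0.935
```

The three generative stem states are placed in the right order along the
inferred axis, and per-cell pseudotime correlates with the true latent
time at ρ = 0.94 on the neural branch.  The numbered scripts under
`analysis/` walk the full study: simulation, detection-vs-depth
diagnostics, normalization + gene selection, clustering, both lineage
trajectories, and the merged-PCA lineage tree; each writes its tables
under `results/`.

The same pipeline is scriptable via the CLI
(`scwaterfall run-all --outdir results/pipeline --seed 0`) or the library
API (`scwaterfall.run_pipeline`).

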