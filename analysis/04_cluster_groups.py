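#!/usr/bin/env python
"""Hierarchical clustering of cells into expression groups.

Euclidean + Ward clustering on the selected variable transcripts, cut into
k = 6 groups (the cohort's six generative states), with gate composition
per group, stem/neural marker summaries, and a rank-sum enrichment scan of
the neural-like group.
"""

from pathlib import Path

import pandas as pd

from scwaterfall import (
    cluster_cells,
    cut_tree,
    group_enriched_genes,
    group_marker_summary,
    normalize,
    read_counts,
    select_hvgs,
)

DATA = Path("results/data")
OUT = Path("results/analysis")
K_GROUPS = 6


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    m = read_counts(DATA / "counts.tsv", "dense-table")
    truth = pd.read_csv(DATA / "truth.tsv", sep="\t", index_col="cell_id")
    nm = normalize(m)
    res = select_hvgs(nm, n_top=300)
    x = nm.log_counts[nm.gene_index(res.selected)].T
    ga = cut_tree(cluster_cells(x, nm.cell_ids), K_GROUPS)
    gates = m.gates()
    ga.to_frame(gates).to_csv(OUT / "groups.tsv", sep="\t")

    comp = pd.crosstab(ga.labels, gates)
    comp.index.name = "group"
    comp.to_csv(OUT / "group_gate_composition.tsv", sep="\t")
    print("gate composition per group:")
    print(comp.to_string())
    xtab = pd.crosstab(ga.labels, truth.loc[nm.cell_ids, "group_true"])
    print("\nagreement with generative states:")
    print(xtab.to_string())

    markers = [f"stem-{i:02d}" for i in (1, 2)] + \
        [f"neural-{i:02d}" for i in (1, 2)]
    summ = group_marker_summary(nm, ga, markers)
    summ.table.to_csv(OUT / "group_marker_summary.tsv", sep="\t",
                      float_format="%.10g")

    # the neural-like group: highest mean neural-marker expression
    neural_mean = summ.table.xs("neural-01", level="gene_id")[
        "mean_log_expression"
    ]
    nu_group = int(neural_mean.idxmax())
    enriched = group_enriched_genes(nm, ga, nu_group)
    enriched.head(25).to_csv(OUT / "nu_group_enriched_genes.tsv", sep="\t",
                             float_format="%.10g")
    top = list(enriched.index[:5])
    print(f"\nneural-like group: {nu_group}; top enriched genes: {top}")


if __name__ == "__main__":
    main()
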