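"""Ground-truth recovery benchmarks for the full pipeline.

These drive the simulator through the complete analysis (normalize ->
variable-gene selection -> Ward clustering -> Waterfall trajectory) and
score the result against the generative truth.  The main-lineage benchmark
mirrors the study design: cluster all cells, keep the clusters whose
majority true state belongs to the stem -> neural lineage (the in-silico
counterpart of picking the stem/neural groups by marker knowledge), run the
trajectory on those cells, and compare inferred pseudotime with truth on
the neural-branch cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import cluster_cells, cut_tree
from .hvg import select_hvgs
from .normalization import normalize
from .synthetic import LineageModel, default_planarian_model, simulate, truth_alignment
from .waterfall import run_waterfall

MAIN_LINEAGE_STATES = ("Group2", "Group1", "nuNeoblast")


@dataclass
class RecoveryResult:
    seed: int
    spearman_main: float        # |rho| on neural-branch cells
    spearman_all: float         # |rho| over every cell in the run
    order_correct: bool         # Group2 < Group1 < nuNeoblast mean pseudotime
    group_mean_pt: dict
    n_cells_run: int
    warnings: list


def main_lineage_recovery(
    seed: int,
    model: LineageModel | None = None,
    n_cells: int = 168,
    n_top: int = 300,
    k_groups: int = 6,
    k_centers: int = 10,
) -> RecoveryResult:
    """One end-to-end run scored against truth.

    Cluster selection uses the ground-truth state labels only to decide
    which clusters form the main lineage (majority state in
    ``MAIN_LINEAGE_STATES``); the trajectory itself never sees the truth.
    """
    if model is None:
        model = default_planarian_model()
    m, truth = simulate(model, n_cells, seed=seed)
    nm = normalize(m)
    hvg_res = select_hvgs(nm, n_top=n_top)
    x = nm.log_counts[nm.gene_index(hvg_res.selected)].T
    ga = cut_tree(cluster_cells(x, nm.cell_ids), k_groups)
    is_main = truth.table["group_true"].isin(MAIN_LINEAGE_STATES).to_numpy()
    keep = [
        g for g in range(1, k_groups + 1)
        if is_main[ga.members(g)].mean() > 0.5
    ]
    wf = run_waterfall(
        nm,
        ga,
        groups=keep,
        genes=hvg_res.selected,
        k=k_centers,
        seed=seed,
        stem_markers=model.marker_panels["stem"][:4],
        lineage_markers=model.marker_panels["neural"][:2],
    )
    al = truth_alignment(wf.pseudotime, truth)
    pt = pd.Series(wf.pseudotime.pseudotime, index=wf.pseudotime.cell_ids)
    states = truth.table.loc[pt.index, "group_true"]
    group_mean = {
        s: float(pt[states == s].mean()) for s in MAIN_LINEAGE_STATES
    }
    ordered = (
        group_mean["Group2"] < group_mean["Group1"] < group_mean["nuNeoblast"]
    )
    return RecoveryResult(
        seed=seed,
        spearman_main=abs(al["branches"]["nu"]["spearman"]),
        spearman_all=abs(al["all"]["spearman"]),
        order_correct=bool(ordered),
        group_mean_pt=group_mean,
        n_cells_run=len(pt),
        warnings=wf.pseudotime.warnings,
    )


def recovery_study(seeds, **kwargs) -> pd.DataFrame:
    """Run :func:`main_lineage_recovery` over many seeds."""
    rows = []
    for s in seeds:
        r = main_lineage_recovery(int(s), **kwargs)
        rows.append(
            {
                "seed": r.seed,
                "spearman_main": r.spearman_main,
                "spearman_all": r.spearman_all,
                "order_correct": r.order_correct,
                "n_cells_run": r.n_cells_run,
            }
        )
    return pd.DataFrame(rows).set_index("seed")


def detection_decline_along_branch(
    model: LineageModel | None = None,
    branch: str = "x2",
    n_grid: int = 12,
    cells_per_point: int = 40,
    seed: int = 0,
) -> pd.DataFrame:
    """Expected detected-transcript count along one branch.

    Simulates cohorts pinned at a grid of pseudotimes on ``branch`` and
    reports the mean number of genes detected (count >= 1) per cell; on the
    differentiation branch this declines as cells leave the stem
    compartment.
    """
    from .counts_io import detection_summary

    if model is None:
        model = default_planarian_model()
    rows = []
    grid = np.linspace(0.02, 0.98, n_grid)
    for i, t in enumerate(grid):
        m, _ = simulate(
            model, cells_per_point, seed=seed * 10_000 + i,
            fixed_t=float(t), fixed_branch=branch,
        )
        det = detection_summary(m, threshold=1)
        rows.append(
            {
                "t": float(t),
                "mean_detected": float(det.per_cell_detected.mean()),
                "mean_total_reads": float(det.per_cell_total_reads.mean()),
            }
        )
    return pd.DataFrame(rows)
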