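"""End-to-end pipeline orchestration and merged-dataset PCA reporting.

A :class:`PipelineConfig` describes one full analysis — input counts (or a
simulation spec), normalization, variable-gene selection, clustering, and a
list of per-lineage trajectory runs — and :func:`run_pipeline` executes it,
writing every table as TSV plus a machine-readable JSON run log that
suffices to re-execute the identical analysis.  All outputs are
deterministic functions of (config, seed); no timestamps or environment
state leak into any file.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import procrustes
from scipy.spatial.distance import cdist

from . import __version__
from .clustering import cluster_cells, cut_tree
from .counts_io import CountsMatrix, detection_summary, read_counts, write_counts
from .hvg import select_hvgs
from .normalization import NormalizedMatrix, normalize
from .synthetic import LineageModel, default_planarian_model, simulate
from .waterfall import run_waterfall

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Pipeline configuration is invalid."""


@dataclass
class WaterfallRunConfig:
    name: str
    groups: object = "x1-majority"   # list of ints or a symbolic selector
    k_centers: int = 10
    endpoints: tuple[int, int] | None = None
    stem_markers: list[str] = field(default_factory=list)
    lineage_markers: list[str] = field(default_factory=list)
    trend_genes: list[str] = field(default_factory=list)
    span: float = 0.75


SYMBOLIC_GROUPS = ("all", "x1-majority", "x2-containing")


@dataclass
class PipelineConfig:
    outdir: str = "results/pipeline"
    seed: int = 0
    # input: either a counts file or a simulation spec
    counts_path: str | None = None
    counts_format: str = "dense-table"
    simulate_n_cells: int | None = None
    simulate_n_genes: int = 1200
    model_path: str | None = None
    # stage parameters
    hvg_n_top: int = 1000
    hvg_mean_floor_log2: float = 3.0
    hvg_n_winsor: int = 2
    k_groups: int = 10
    waterfall_runs: list[WaterfallRunConfig] = field(default_factory=list)
    write_counts_copy: bool = False

    def validate(self) -> None:
        if (self.counts_path is None) == (self.simulate_n_cells is None):
            raise ConfigError(
                "exactly one of counts_path or simulate_n_cells is required"
            )
        if self.k_groups < 1:
            raise ConfigError("k_groups must be >= 1")
        for run in self.waterfall_runs:
            if isinstance(run.groups, str):
                if run.groups not in SYMBOLIC_GROUPS:
                    raise ConfigError(
                        f"run {run.name!r}: unknown symbolic group selector "
                        f"{run.groups!r} (allowed: {SYMBOLIC_GROUPS})"
                    )
            else:
                bad = [g for g in run.groups if not 1 <= int(g) <= self.k_groups]
                if bad:
                    raise ConfigError(
                        f"run {run.name!r} references group(s) {bad} outside "
                        f"1..{self.k_groups}"
                    )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["waterfall_runs"] = [asdict(r) for r in self.waterfall_runs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        runs = [
            WaterfallRunConfig(**{
                **r,
                "endpoints": tuple(r["endpoints"]) if r.get("endpoints") else None,
            })
            for r in d.pop("waterfall_runs", [])
        ]
        return cls(waterfall_runs=runs, **d)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


def default_synthetic_config(outdir: str, seed: int = 0) -> PipelineConfig:
    """The stock configuration: simulate the default cohort and run both
    lineage trajectories with the built-in marker panels."""
    model = default_planarian_model()
    stem = model.marker_panels["stem"]
    neural = model.marker_panels["neural"]
    return PipelineConfig(
        outdir=outdir,
        seed=seed,
        simulate_n_cells=168,
        hvg_n_top=300,
        k_groups=6,
        waterfall_runs=[
            WaterfallRunConfig(
                name="main-lineage",
                groups="x1-majority",
                k_centers=10,
                stem_markers=stem[:4],
                lineage_markers=neural[:2],
                trend_genes=[stem[0], neural[0], "transition-peak-01"],
            ),
        ],
    )


def _resolve_groups(selector, ga, gates: np.ndarray) -> list[int]:
    if not isinstance(selector, str):
        return [int(g) for g in selector]
    if selector == "all":
        return list(range(1, ga.k + 1))
    chosen = []
    for g in range(1, ga.k + 1):
        frac_x2 = float((gates[ga.members(g)] == "X2").mean())
        if selector == "x1-majority" and frac_x2 < 0.5:
            chosen.append(g)
        elif selector == "x2-containing" and frac_x2 > 0.0:
            chosen.append(g)
    if not chosen:
        raise ConfigError(f"symbolic selector {selector!r} matched no group")
    return chosen


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured analysis; returns the report bundle.

    The bundle maps stage names to in-memory artifacts and is also fully
    serialized under ``cfg.outdir``.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "version": __version__,
        "config": cfg.to_dict(),
        "warnings": [],
        "stages": [],
    }

    def stage(name):
        log["stages"].append(name)
        logger.info("pipeline stage: %s", name)

    truth = None
    if cfg.simulate_n_cells is not None:
        stage("simulate")
        model = (
            LineageModel.load(cfg.model_path)
            if cfg.model_path
            else default_planarian_model(cfg.simulate_n_genes)
        )
        m, truth = simulate(model, cfg.simulate_n_cells, seed=cfg.seed)
        truth.export(outdir / "truth.tsv")
        if cfg.write_counts_copy:
            write_counts(m, outdir / "counts.tsv", "dense-table")
    else:
        stage("read-counts")
        m = read_counts(cfg.counts_path, cfg.counts_format)

    stage("detection-summary")
    det = detection_summary(m, threshold=1)
    det.to_frame().to_csv(outdir / "detection_summary.tsv", sep="\t")

    stage("normalize")
    nm = normalize(m)
    nm.export_size_factors(outdir / "size_factors.tsv")

    stage("hvg")
    hvg_res = select_hvgs(
        nm,
        n_top=cfg.hvg_n_top,
        mean_floor_log2=cfg.hvg_mean_floor_log2,
        n_winsor=cfg.hvg_n_winsor,
    )
    hvg_res.export(outdir / "hvg_report.tsv")

    stage("cluster")
    x = nm.log_counts[nm.gene_index(hvg_res.selected)].T
    dend = cluster_cells(x, nm.cell_ids)
    ga = cut_tree(dend, cfg.k_groups)
    gates = m.gates()
    ga.to_frame(gates).to_csv(outdir / "groups.tsv", sep="\t")

    group_summary = []
    for g in range(1, ga.k + 1):
        members = ga.members(g)
        group_summary.append(
            {
                "group": g,
                "n_cells": int(members.size),
                "frac_X1": float((gates[members] == "X1").mean()),
                "frac_X2": float((gates[members] == "X2").mean()),
            }
        )

    runs_out = {}
    for run in cfg.waterfall_runs:
        stage(f"waterfall:{run.name}")
        groups = _resolve_groups(run.groups, ga, gates)
        wf = run_waterfall(
            nm,
            ga,
            groups=groups,
            genes=hvg_res.selected,
            k=run.k_centers,
            seed=cfg.seed,
            stem_markers=run.stem_markers or None,
            lineage_markers=run.lineage_markers or None,
            trend_genes=run.trend_genes,
            endpoints=run.endpoints,
            span=run.span,
        )
        cell_groups = ga.to_frame().loc[wf.cells_used, "group"].to_numpy()
        wf.pseudotime.to_frame(cell_groups).to_csv(
            outdir / f"{run.name}_pseudotime.tsv", sep="\t",
            float_format="%.10g",
        )
        for gene, trend in wf.trends.items():
            trend.export(outdir / f"{run.name}_trend_{gene}.tsv")
        for w in wf.pseudotime.warnings:
            log["warnings"].append({"run": run.name, **w})
        runs_out[run.name] = wf
        log.setdefault("runs", {})[run.name] = {
            "groups_resolved": groups,
            "orientation": wf.pseudotime.graph.orientation,
            "n_cells": len(wf.cells_used),
        }

    summary = {
        "n_genes": m.n_genes,
        "n_cells": m.n_cells,
        "mean_detected_per_cell": float(det.per_cell_detected.mean()),
        "groups": group_summary,
        "n_hvg_selected": len(hvg_res.selected),
    }
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True)
    )
    (outdir / "run_log.json").write_text(
        json.dumps(log, indent=1, sort_keys=True, default=str)
    )
    return {
        "counts": m,
        "truth": truth,
        "normalized": nm,
        "hvg": hvg_res,
        "groups": ga,
        "runs": runs_out,
        "summary": summary,
        "log": log,
    }


# ---------------------------------------------------------------------------
# merged-dataset PCA reporting


def merged_pca_report(
    matrices: list[tuple[NormalizedMatrix, np.ndarray]],
    n_top: int = 1000,
    exclude_groups: list = (),
    mean_floor_log2: float = 3.0,
) -> dict:
    """Global lineage-tree view: merged HVG selection + PCA.

    ``matrices`` pairs each normalized matrix with a per-cell group label
    vector.  Genes are intersected across datasets, variable genes are
    re-selected on the merged matrix, and PCA scores plus per-group
    centroids and their pairwise distances are returned.  ``exclude_groups``
    supports lineage-removal reruns.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    shared = set(matrices[0][0].gene_ids)
    for nm, _ in matrices[1:]:
        shared &= set(nm.gene_ids)
    if not shared:
        raise ValueError("empty gene intersection across datasets")
    shared = sorted(shared)

    norm_blocks, log_blocks, labels, cell_ids = [], [], [], []
    for di, (nm, groups) in enumerate(matrices):
        groups = np.asarray(groups)
        keep = ~np.isin(groups, list(exclude_groups))
        idx = nm.gene_index(shared)
        norm_blocks.append(nm.norm_counts[np.ix_(idx, np.flatnonzero(keep))])
        log_blocks.append(nm.log_counts[np.ix_(idx, np.flatnonzero(keep))])
        labels.extend(groups[keep])
        cell_ids.extend(f"d{di}:{c}" for c, k in zip(nm.cell_ids, keep) if k)
    merged = NormalizedMatrix(
        gene_ids=shared,
        cell_ids=cell_ids,
        size_factors=np.ones(len(cell_ids)),
        norm_counts=np.concatenate(norm_blocks, axis=1),
        log_counts=np.concatenate(log_blocks, axis=1),
    )
    hvg_res = select_hvgs(merged, n_top=n_top, mean_floor_log2=mean_floor_log2)
    from .waterfall import pca as _pca

    x = merged.log_counts[merged.gene_index(hvg_res.selected)].T
    pres = _pca(x, n_pcs=2)
    labels = np.asarray(labels)
    uniq = sorted(set(labels.tolist()))
    centroids = np.array(
        [pres.scores[labels == g].mean(axis=0) for g in uniq]
    )
    dist = cdist(centroids, centroids)
    return {
        "scores": pres.scores,
        "labels": labels,
        "cell_ids": cell_ids,
        "hvg": hvg_res,
        "group_order": uniq,
        "centroids": centroids,
        "centroid_distances": pd.DataFrame(dist, index=uniq, columns=uniq),
    }


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Shape dissimilarity of two point sets after optimal alignment."""
    _, _, d = procrustes(np.asarray(a, float), np.asarray(b, float))
    return float(d)
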