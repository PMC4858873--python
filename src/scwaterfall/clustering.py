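"""Hierarchical clustering of cells into expression groups.

Cells (observations) are clustered on log2 normalized expression over the
selected highly variable genes: Euclidean distances, Ward agglomeration in
the ward.D2 convention (merge heights on the distance scale), and a k-group
dendrogram cut.  A t-SNE embedding is provided strictly for visualization;
no downstream inference reads it.  Marker summaries and a rank-sum
enrichment utility describe the resulting groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import TSNE

from .normalization import NormalizedMatrix

logger = logging.getLogger(__name__)


def distance_matrix(x: np.ndarray) -> np.ndarray:
    """Symmetric Euclidean distance matrix between cell rows."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] == 0:
        raise ValueError("need a cells x genes matrix with at least one gene")
    if np.any(~np.isfinite(x)):
        raise ValueError("missing or non-finite values in expression matrix")
    return squareform(pdist(x, metric="euclidean"))


@dataclass
class Dendrogram:
    """Agglomeration record: scipy linkage matrix plus leaf ids."""

    linkage: np.ndarray  # (n-1, 4) scipy format
    leaf_ids: list[str]

    def __post_init__(self) -> None:
        n = len(self.leaf_ids)
        if self.linkage.shape != (n - 1, 4):
            raise ValueError("linkage shape does not match number of leaves")
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValueError("merge heights are not non-decreasing")

    @property
    def merges(self) -> list[tuple[int, int, float]]:
        return [
            (int(a), int(b), float(h)) for a, b, h, _ in self.linkage
        ]


def ward_linkage(d: np.ndarray) -> Dendrogram:
    """Ward agglomeration on a Euclidean distance matrix (ward.D2).

    Heights are on the distance scale: the height of a merge is the
    square root of twice the increase in within-cluster sum of squares,
    matching R's hclust(method="ward.D2") on Euclidean distances.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    condensed = squareform(d, checks=False)
    Z = hierarchy.linkage(condensed, method="ward")
    return Dendrogram(linkage=Z, leaf_ids=[str(i) for i in range(d.shape[0])])


def cluster_cells(x: np.ndarray, cell_ids: list[str]) -> Dendrogram:
    """Convenience: Euclidean distances + Ward linkage with real cell ids."""
    d = distance_matrix(x)
    dend = ward_linkage(d)
    return Dendrogram(linkage=dend.linkage, leaf_ids=list(cell_ids))


@dataclass
class GroupAssignment:
    """Per-cell group label in 1..k, numbered by first leaf appearance."""

    cell_ids: list[str]
    labels: np.ndarray
    k: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.cell_ids),):
            raise ValueError("one label per cell required")
        present = set(self.labels.tolist())
        if present != set(range(1, self.k + 1)):
            raise ValueError(
                f"labels must cover 1..{self.k}; saw {sorted(present)}"
            )

    def members(self, group: int) -> np.ndarray:
        return np.flatnonzero(self.labels == group)

    def to_frame(self, gates=None) -> pd.DataFrame:
        out = pd.DataFrame(
            {"group": self.labels},
            index=pd.Index(self.cell_ids, name="cell_id"),
        )
        if gates is not None:
            out["gate"] = np.asarray(gates)
        return out


def cut_tree(dend: Dendrogram, k: int) -> GroupAssignment:
    """Cut the dendrogram into k groups (remove the k-1 highest merges)."""
    n = len(dend.leaf_ids)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    raw = hierarchy.cut_tree(dend.linkage, n_clusters=k).ravel()
    # renumber by order of first appearance over the leaves
    relabel: dict[int, int] = {}
    for lab in raw:
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
    labels = np.array([relabel[lab] for lab in raw], dtype=int)
    return GroupAssignment(
        cell_ids=list(dend.leaf_ids),
        labels=labels,
        k=k,
        provenance={"metric": "euclidean", "linkage": "ward.D2", "k": k},
    )


def embed_2d(
    x: np.ndarray, seed: int = 0, perplexity: float = 30.0
) -> np.ndarray:
    """2-D t-SNE embedding, deterministic given the seed.

    Visualization only: trajectory inference never reads these coordinates.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n <= 3 * perplexity:
        raise ValueError(
            f"perplexity {perplexity} too large for {n} cells "
            f"(need n > 3 x perplexity)"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
    )
    return tsne.fit_transform(x)


@dataclass
class GroupMarkerTable:
    """Mean log expression and detection fraction per (group, marker)."""

    table: pd.DataFrame  # MultiIndex (group, gene_id)
    missing: list[str]


def group_marker_summary(
    nm: NormalizedMatrix, ga: GroupAssignment, markers: list[str]
) -> GroupMarkerTable:
    """Summarize marker expression per group.

    Detection fraction is the share of a group's cells with raw count >= 1;
    it therefore needs the source CountsMatrix on ``nm``.
    """
    present = [g for g in markers if g in nm.gene_ids]
    missing = [g for g in markers if g not in nm.gene_ids]
    if missing:
        logger.warning("markers absent from matrix: %s", missing)
    gidx = nm.gene_index(present)
    raw = nm.source.counts if nm.source is not None else nm.norm_counts
    rows = []
    for group in range(1, ga.k + 1):
        cells = ga.members(group)
        for g, gi in zip(present, gidx):
            rows.append(
                {
                    "group": group,
                    "gene_id": g,
                    "mean_log_expression": float(
                        nm.log_counts[gi, cells].mean()
                    ),
                    "detection_fraction": float(
                        (raw[gi, cells] >= 1).mean()
                    ),
                }
            )
    if rows:
        table = pd.DataFrame(rows).set_index(["group", "gene_id"])
    else:
        table = pd.DataFrame(
            columns=["mean_log_expression", "detection_fraction"],
            index=pd.MultiIndex.from_arrays([[], []], names=["group", "gene_id"]),
        )
    return GroupMarkerTable(table=table, missing=missing)


def group_enriched_genes(
    nm: NormalizedMatrix, ga: GroupAssignment, group: int
) -> pd.DataFrame:
    """Rank genes by a group-vs-rest rank-sum statistic on log expression.

    The standardized Wilcoxon rank-sum statistic (normal approximation with
    tie correction) is positive for genes higher in the group.  Ties in the
    statistic are broken by descending mean log expression then gene id.
    """
    if group not in range(1, ga.k + 1):
        raise ValueError(f"group {group} does not exist")
    in_idx = ga.members(group)
    out_idx = np.flatnonzero(ga.labels != group)
    if len(in_idx) < 2 or len(out_idx) < 2:
        raise ValueError("need at least 2 cells inside and outside the group")
    zs = np.zeros(nm.n_genes)
    for gi in range(nm.n_genes):
        a = nm.log_counts[gi, in_idx]
        b = nm.log_counts[gi, out_idx]
        if np.ptp(np.concatenate([a, b])) == 0:
            zs[gi] = 0.0
            continue
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        n1, n2 = len(a), len(b)
        mu = n1 * n2 / 2.0
        combined = np.concatenate([a, b])
        _, tie_counts = np.unique(combined, return_counts=True)
        n = n1 + n2
        tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
        sigma = np.sqrt(n1 * n2 / 12.0 * (n + 1 - tie_term))
        zs[gi] = (res.statistic - mu) / sigma if sigma > 0 else 0.0
    tab = pd.DataFrame(
        {
            "z": zs,
            "mean_log_expression": nm.log_counts[:, in_idx].mean(axis=1),
        },
        index=pd.Index(nm.gene_ids, name="gene_id"),
    )
    tab = tab.sort_values(
        by=["z", "mean_log_expression", "gene_id"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    tab["rank"] = np.arange(1, len(tab) + 1)
    return tab
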