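"""Waterfall trajectory reconstruction: PCA -> k-means -> MST -> pseudotime.

The trajectory model is deliberately simple: cells are embedded by PCA on
log2 normalized expression of the selected variable genes, k-means centers
summarize the cloud, a Euclidean minimum spanning tree connects the centers,
and one path through that tree (between chosen endpoints, or the tree's
diameter) is the lineage axis.  Each cell is projected orthogonally onto the
polyline through the ordered centers; its pseudotime is the normalized arc
length from the root to the projection, clamped to the ends.  Orientation
(which end is the root) is decided by stem-cell marker expression at the two
terminal centers, optionally cross-checked against differentiation-lineage
markers.  The residual distance stored per cell is its Euclidean distance to
the nearest k-means center — the quantity plotted on the y axis of
pseudotime figures — kept alongside the orthogonal projection residual.

Branching trees are handled one lineage at a time: the caller subsets the
cell groups for each lineage and, if the MST still branches, supplies
explicit endpoints; off-path centers trigger a structured warning.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree as _sp_mst
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .clustering import GroupAssignment
from .normalization import NormalizedMatrix
from .trends import GeneTrend, gene_trend

logger = logging.getLogger(__name__)


class OrientationError(ValueError):
    """Marker scores tie; explicit endpoints are required."""


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PcaResult:
    scores: np.ndarray          # cells x n_pcs
    loadings: np.ndarray        # genes x n_pcs, orthonormal columns
    variance_explained: np.ndarray
    center: np.ndarray          # per-gene mean used for centering

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.center) @ self.loadings


def pca(x: np.ndarray, n_pcs: int = 2) -> PcaResult:
    """PCA by SVD on gene-wise mean-centered data (no scaling).

    Sign convention: each loading column's largest-magnitude entry is
    positive, so results are reproducible across SVD implementations.
    """
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    if n_pcs > min(n - 1, p):
        raise ValueError(
            f"n_pcs={n_pcs} exceeds min(cells-1, genes)={min(n - 1, p)}"
        )
    center = x.mean(axis=0)
    xc = x - center
    total_var = np.sum(xc**2)
    if total_var == 0:
        raise ValueError("constant matrix: no variance to decompose")
    U, S, Vt = np.linalg.svd(xc, full_matrices=False)
    loadings = Vt[:n_pcs].T.copy()
    for j in range(n_pcs):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
    scores = xc @ loadings
    var_exp = (S[:n_pcs] ** 2) / total_var
    return PcaResult(
        scores=scores,
        loadings=loadings,
        variance_explained=var_exp,
        center=center,
    )


# ---------------------------------------------------------------------------
# k-means centers and MST


def kmeans_centers(
    scores: np.ndarray, k: int, seed: int = 0, n_restarts: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """k-means++ / Lloyd, best of ``n_restarts`` by inertia.

    Returns (centers, per-cell nearest-center assignment); deterministic
    given the seed.
    """
    scores = np.asarray(scores, dtype=float)
    if k > scores.shape[0]:
        raise ValueError(f"k={k} exceeds number of cells {scores.shape[0]}")
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=n_restarts, random_state=seed
    ).fit(scores)
    return km.cluster_centers_, km.labels_


def mst(centers: np.ndarray) -> list[tuple[int, int, float]]:
    """Euclidean minimum spanning tree over the centers.

    Edges are returned as (i, j, length) with i < j, sorted
    lexicographically.
    """
    centers = np.asarray(centers, dtype=float)
    k = centers.shape[0]
    if k < 2:
        raise ValueError("need at least 2 centers")
    d = cdist(centers, centers)
    if np.any(d[np.triu_indices(k, 1)] == 0):
        raise ValueError("duplicate centers")
    tree = _sp_mst(d).tocoo()
    edges = sorted(
        (min(int(i), int(j)), max(int(i), int(j)), float(v))
        for i, j, v in zip(tree.row, tree.col, tree.data)
    )
    return edges


def _tree_graph(edges) -> nx.Graph:
    g = nx.Graph()
    for i, j, w in edges:
        g.add_edge(i, j, weight=w)
    return g


def linearize(
    edges: list[tuple[int, int, float]],
    endpoints: tuple[int, int] | None = None,
) -> tuple[list[int], list[int]]:
    """Extract the lineage path through the MST.

    With explicit ``endpoints`` the unique tree path between them is
    returned; otherwise the weighted diameter path.  Returns
    (path, off_path_centers); a nonempty second element signals branching.
    """
    g = _tree_graph(edges)
    nodes = sorted(g.nodes)
    if endpoints is not None:
        a, b = endpoints
        if a not in g or b not in g:
            raise ValueError(f"endpoints {endpoints} not in the tree")
        path = nx.shortest_path(g, a, b, weight="weight")
    else:
        # weighted diameter: farthest pair by tree distance, deterministic
        lengths = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
        best = max(
            (
                (lengths[u][v], (u, v))
                for u, v in itertools.combinations(nodes, 2)
            ),
            key=lambda t: (t[0], (-t[1][0], -t[1][1])),
        )
        path = nx.shortest_path(g, *best[1], weight="weight")
    off_path = [n for n in nodes if n not in set(path)]
    if off_path:
        logger.warning(
            "trajectory branches: centers %s lie off the linearized path",
            off_path,
        )
    return list(path), off_path


def orient(
    path: list[int],
    assignment: np.ndarray,
    stem_score: np.ndarray,
    lineage_score: np.ndarray | None = None,
) -> tuple[list[int], list[dict]]:
    """Point the path root-first using marker expression.

    ``stem_score``/``lineage_score`` are per-cell scalars (e.g. mean log
    expression of stem-cell or differentiation markers);  the root is the
    terminal center whose assigned cells have the higher mean stem score.
    If lineage markers are supplied and disagree (higher at the root), the
    stem decision stands and a structured conflict warning is returned.
    """
    assignment = np.asarray(assignment)
    stem_score = np.asarray(stem_score, dtype=float)
    warnings_out: list[dict] = []
    ends = (path[0], path[-1])
    means = []
    for c in ends:
        cells = np.flatnonzero(assignment == c)
        if cells.size == 0:
            raise OrientationError(
                f"terminal center {c} has no assigned cells; "
                "supply explicit endpoints"
            )
        means.append(float(stem_score[cells].mean()))
    if means[0] == means[1]:
        raise OrientationError(
            "stem-marker scores tie at the two terminals; "
            "supply explicit endpoints"
        )
    oriented = list(path) if means[0] > means[1] else list(reversed(path))
    if lineage_score is not None:
        lmeans = []
        for c in (oriented[0], oriented[-1]):
            cells = np.flatnonzero(assignment == c)
            lmeans.append(float(np.asarray(lineage_score, float)[cells].mean()))
        if lmeans[0] >= lmeans[-1]:
            warnings_out.append(
                {
                    "kind": "orientation-conflict",
                    "detail": "lineage markers are not higher at the "
                    "non-root terminal; keeping stem-marker orientation",
                    "root_lineage_score": lmeans[0],
                    "terminal_lineage_score": lmeans[-1],
                }
            )
            logger.warning("%s", warnings_out[-1]["detail"])
    return oriented, warnings_out


# ---------------------------------------------------------------------------
# pseudotime assignment


@dataclass
class TrajectoryGraph:
    centers: np.ndarray
    mst_edges: list[tuple[int, int, float]]
    path: list[int]
    orientation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        k = self.centers.shape[0]
        if len(self.mst_edges) != k - 1:
            raise ValueError("MST must have k-1 edges")
        adj = {(i, j) for i, j, _ in self.mst_edges}
        adj |= {(j, i) for i, j in adj}
        if len(set(self.path)) != len(self.path):
            raise ValueError("path revisits a center")
        for a, b in zip(self.path, self.path[1:]):
            if (a, b) not in adj:
                raise ValueError(f"path step {a}->{b} is not an MST edge")


@dataclass
class PseudotimeResult:
    cell_ids: list[str]
    pseudotime: np.ndarray          # in [0, 1]
    raw_pseudotime: np.ndarray      # arc length before normalization
    residual_distance: np.ndarray   # distance to nearest k-means center
    projection_residual: np.ndarray  # orthogonal distance to the polyline
    segment: np.ndarray             # index of the polyline segment used
    center_assignment: np.ndarray   # nearest k-means center per cell
    graph: TrajectoryGraph
    provenance: dict = field(default_factory=dict)
    warnings: list[dict] = field(default_factory=list)

    def to_frame(self, groups=None) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "pseudotime": self.pseudotime,
                "residual_distance": self.residual_distance,
                "segment": self.segment,
            },
            index=pd.Index(self.cell_ids, name="cell_id"),
        )
        if groups is not None:
            out.insert(0, "group", np.asarray(groups))
        return out


def _project_to_polyline(points: np.ndarray, verts: np.ndarray):
    """Orthogonal projection of each point onto the polyline.

    Returns (arc_length, orthogonal_residual, segment_index); arc length is
    clamped to [0, total length].
    """
    seg_vec = np.diff(verts, axis=0)
    seg_len = np.linalg.norm(seg_vec, axis=1)
    if np.all(seg_len == 0):
        raise ValueError("degenerate polyline of zero length")
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    arc = np.empty(points.shape[0])
    resid = np.empty(points.shape[0])
    seg_idx = np.empty(points.shape[0], dtype=int)
    for ci, p in enumerate(points):
        best = (np.inf, 0.0, 0)
        for si in range(len(seg_vec)):
            if seg_len[si] == 0:
                continue
            t = np.dot(p - verts[si], seg_vec[si]) / seg_len[si] ** 2
            t = np.clip(t, 0.0, 1.0)
            proj = verts[si] + t * seg_vec[si]
            dist = float(np.linalg.norm(p - proj))
            if dist < best[0] - 1e-12:
                best = (dist, cum[si] + t * seg_len[si], si)
        resid[ci], arc[ci], seg_idx[ci] = best
    return arc, resid, seg_idx


def assign_pseudotime(
    scores: np.ndarray,
    tg: TrajectoryGraph,
    cell_ids: list[str] | None = None,
    center_assignment: np.ndarray | None = None,
) -> PseudotimeResult:
    """Project cells onto the oriented center polyline.

    Pseudotime is arc length from the root to each cell's orthogonal
    projection, normalized by the polyline's total length; cells beyond
    either end clamp to 0 or 1.
    """
    scores = np.asarray(scores, dtype=float)
    verts = tg.centers[tg.path]
    arc, resid, seg_idx = _project_to_polyline(scores, verts)
    total = float(
        np.sum(np.linalg.norm(np.diff(verts, axis=0), axis=1))
    )
    if total == 0:
        raise ValueError("degenerate polyline of zero length")
    d_centers = cdist(scores, tg.centers)
    nearest = np.argmin(d_centers, axis=1)
    if center_assignment is not None:
        nearest = np.asarray(center_assignment)
    residual_distance = d_centers[np.arange(scores.shape[0]), nearest]
    if cell_ids is None:
        cell_ids = [str(i) for i in range(scores.shape[0])]
    return PseudotimeResult(
        cell_ids=list(cell_ids),
        pseudotime=np.clip(arc / total, 0.0, 1.0),
        raw_pseudotime=arc,
        residual_distance=residual_distance,
        projection_residual=resid,
        segment=seg_idx,
        center_assignment=nearest,
        graph=tg,
    )


# ---------------------------------------------------------------------------
# composed run


def marker_score(nm: NormalizedMatrix, markers: list[str]) -> np.ndarray:
    """Mean log2 normalized expression over a marker panel, per cell."""
    present = [g for g in markers if g in nm.gene_ids]
    if not present:
        raise ValueError(f"no marker of {markers} present in the matrix")
    idx = nm.gene_index(present)
    return nm.log_counts[idx].mean(axis=0)


@dataclass
class WaterfallResult:
    pseudotime: PseudotimeResult
    pca: PcaResult
    trends: dict[str, GeneTrend]
    cells_used: list[str]
    groups_used: list[int]
    provenance: dict = field(default_factory=dict)


def run_waterfall(
    nm: NormalizedMatrix,
    ga: GroupAssignment,
    groups: list[int],
    genes: list[str] | None = None,
    k: int = 10,
    seed: int = 0,
    n_pcs: int = 2,
    n_restarts: int = 10,
    stem_markers: list[str] | None = None,
    lineage_markers: list[str] | None = None,
    trend_genes: list[str] | None = None,
    endpoints: tuple[int, int] | None = None,
    span: float = 0.75,
) -> WaterfallResult:
    """Full trajectory run on a subset of cell groups.

    Composes PCA -> k-means -> MST -> linearize -> orient ->
    pseudotime projection on the cells of ``groups``, using log2
    expression of ``genes`` (default: all genes in ``nm``, typically
    already the selected variable genes).  When ``endpoints`` is given the
    path is forced between those centers and orientation runs from
    ``endpoints[0]`` as root unless stem markers override.
    """
    if not groups:
        raise ValueError("groups must be nonempty")
    mask = np.isin(ga.labels, groups)
    cell_idx = np.flatnonzero(mask)
    if cell_idx.size < k:
        raise ValueError(
            f"only {cell_idx.size} cells in groups {groups}; need >= k={k}"
        )
    sub = nm.subset_cells(cell_idx)
    if genes is None:
        genes = list(sub.gene_ids)
    x = sub.log_counts[sub.gene_index(genes)].T  # cells x genes
    pres = pca(x, n_pcs=n_pcs)
    centers, km_assign = kmeans_centers(
        pres.scores, k=k, seed=seed, n_restarts=n_restarts
    )
    edges = mst(centers)
    path, off_path = linearize(edges, endpoints=endpoints)
    warnings_out: list[dict] = []
    if off_path:
        warnings_out.append(
            {"kind": "branching", "off_path_centers": off_path}
        )
    orientation = {}
    if stem_markers:
        stem = marker_score(sub, stem_markers)
        lineage = (
            marker_score(sub, lineage_markers) if lineage_markers else None
        )
        path, conflicts = orient(path, km_assign, stem, lineage)
        warnings_out.extend(conflicts)
        orientation = {"root": path[0], "terminal": path[-1],
                       "decided_by": "stem-markers"}
    elif endpoints is not None:
        orientation = {"root": path[0], "terminal": path[-1],
                       "decided_by": "explicit-endpoints"}
    tg = TrajectoryGraph(
        centers=centers, mst_edges=edges, path=path, orientation=orientation
    )
    pt = assign_pseudotime(
        pres.scores, tg, cell_ids=sub.cell_ids, center_assignment=km_assign
    )
    pt.provenance = {
        "k": k,
        "seed": seed,
        "groups": list(groups),
        "n_pcs": n_pcs,
        "n_genes": len(genes),
    }
    pt.warnings = warnings_out
    trends: dict[str, GeneTrend] = {}
    for g in trend_genes or []:
        if g not in sub.gene_ids:
            warnings_out.append({"kind": "missing-trend-gene", "gene": g})
            continue
        expr = sub.log_counts[sub.gene_index([g])[0]]
        trends[g] = gene_trend(pt.pseudotime, expr, span=span)
    return WaterfallResult(
        pseudotime=pt,
        pca=pres,
        trends=trends,
        cells_used=list(sub.cell_ids),
        groups_used=list(groups),
        provenance=dict(pt.provenance),
    )
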