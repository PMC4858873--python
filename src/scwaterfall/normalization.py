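"""Median-of-ratios size-factor normalization and log transformation.

Sequencing depth and library composition differ between cells, so raw counts
are divided by a per-cell size factor before any cross-cell comparison.  The
estimator is the classical median-of-ratios: for each cell, the median over
reference genes of the ratio of that cell's count to the gene's geometric
mean across cells.  The reference set is the genes detected in every cell
(those with strictly positive counts everywhere); no post-hoc rescaling is
applied, so the factors are exactly the plain estimator's output.
Downstream analyses use log2(normalized count + 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .counts_io import CountsMatrix


class EmptyReferenceSetError(ValueError):
    """No gene has nonzero counts in every cell.

    Filter genes/cells first or supply externally computed size factors.
    """


@dataclass
class NormalizedMatrix:
    """Size factors plus normalized and log2-transformed expression."""

    gene_ids: list[str]
    cell_ids: list[str]
    size_factors: np.ndarray
    norm_counts: np.ndarray
    log_counts: np.ndarray
    source: CountsMatrix | None = None

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def cell_meta(self) -> pd.DataFrame:
        if self.source is None:
            raise AttributeError("no source CountsMatrix attached")
        return self.source.cell_meta

    def gene_index(self, gene_ids) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in lookup]
        if missing:
            raise KeyError(f"genes not present: {missing}")
        return np.array([lookup[g] for g in gene_ids], dtype=int)

    def subset_cells(self, idx) -> "NormalizedMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return NormalizedMatrix(
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in idx],
            size_factors=self.size_factors[idx],
            norm_counts=self.norm_counts[:, idx],
            log_counts=self.log_counts[:, idx],
            source=self.source.subset_cells(idx) if self.source else None,
        )

    def export_size_factors(self, path) -> Path:
        path = Path(path)
        pd.DataFrame(
            {"size_factor": self.size_factors},
            index=pd.Index(self.cell_ids, name="cell_id"),
        ).to_csv(path, sep="\t", float_format="%.10g")
        return path


def size_factors(m: CountsMatrix) -> np.ndarray:
    """Median-of-ratios size factor per cell.

    sf[j] = median over reference genes g of counts[g, j] / geomean_g,
    where the reference set is the genes with strictly positive counts in
    all cells and geomean_g is gene g's geometric mean across cells.
    """
    counts = np.asarray(m.counts, dtype=float)
    reference = np.all(counts > 0, axis=1)
    if not np.any(reference):
        raise EmptyReferenceSetError(
            "no gene is detected in every cell; filter genes to a common "
            "detected set or supply size factors computed elsewhere"
        )
    ref = counts[reference]
    log_geomean = np.mean(np.log(ref), axis=1, keepdims=True)
    ratios = np.exp(np.log(ref) - log_geomean)
    sf = np.median(ratios, axis=0)
    if np.any(~np.isfinite(sf)) or np.any(sf <= 0):
        raise EmptyReferenceSetError("degenerate size factors from reference set")
    return sf


def normalize(m: CountsMatrix, sf: np.ndarray | None = None) -> NormalizedMatrix:
    """Divide counts by size factors; attach log2(x + 1) expression."""
    if sf is None:
        sf = size_factors(m)
    sf = np.asarray(sf, dtype=float)
    if sf.shape != (m.n_cells,):
        raise ValueError(
            f"expected {m.n_cells} size factors, got shape {sf.shape}"
        )
    if np.any(sf <= 0) or np.any(~np.isfinite(sf)):
        raise ValueError("size factors must be strictly positive and finite")
    norm = m.counts / sf[np.newaxis, :]
    return NormalizedMatrix(
        gene_ids=list(m.gene_ids),
        cell_ids=list(m.cell_ids),
        size_factors=sf,
        norm_counts=norm,
        log_counts=np.log2(norm + 1.0),
        source=m,
    )
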