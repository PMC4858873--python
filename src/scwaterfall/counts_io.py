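"""Count-matrix containers, readers/writers, and per-cell detection summaries.

The pipeline starts from a raw integer count matrix (transcripts as rows,
cells as columns) with per-cell FACS-gate metadata.  Two on-disk dialects are
supported: a dense tab-separated table (gene id in column 1, header row of
cell ids) and MatrixMarket coordinate format with plain-text sidecar id
lists.  Per-cell detection summaries (number of transcripts at or above a
detection threshold, total assigned reads) feed the sequencing-depth
diagnostics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from scipy import stats

logger = logging.getLogger(__name__)

VALID_GATES = ("X1", "X2", "other")

#: accepted format names; the long names are canonical
DENSE_FORMATS = ("dense-table", "dense", "tsv")
SPARSE_FORMATS = ("sparse-triplet", "mtx", "sparse")


class CountsFormatError(ValueError):
    """A counts file does not parse in the requested dialect."""


class CountsValidationError(ValueError):
    """Parsed data violate the count-matrix invariants."""


class UndefinedCorrelationError(ValueError):
    """Pearson correlation requested on a zero-variance vector."""


def _normalize_gate(gate: object) -> str:
    g = str(gate)
    if g in VALID_GATES:
        return g
    logger.warning("unknown gate label %r mapped to 'other'", gate)
    return "other"


@dataclass
class CountsMatrix:
    """Raw integer counts, genes x cells, plus per-cell metadata.

    ``cell_meta`` is a DataFrame indexed by cell id with columns
    ``gate`` (one of X1/X2/other), ``region`` and ``source`` (free text).
    """

    gene_ids: list[str]
    cell_ids: list[str]
    counts: np.ndarray
    cell_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.counts = np.asarray(self.counts)
        if self.cell_meta is None:
            self.cell_meta = default_cell_meta(self.cell_ids)
        self.validate()

    def validate(self) -> None:
        n_genes, n_cells = len(self.gene_ids), len(self.cell_ids)
        if self.counts.shape != (n_genes, n_cells):
            raise CountsValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"({n_genes} genes, {n_cells} cells)"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise CountsValidationError("gene ids are not unique")
        if len(set(self.cell_ids)) != n_cells:
            raise CountsValidationError("cell ids are not unique")
        if self.counts.size:
            if not np.issubdtype(self.counts.dtype, np.number):
                raise CountsValidationError("counts are not numeric")
            if np.any(self.counts < 0):
                g, c = np.argwhere(self.counts < 0)[0]
                raise CountsValidationError(
                    f"negative count at gene {self.gene_ids[g]!r}, "
                    f"cell {self.cell_ids[c]!r}"
                )
            if not np.issubdtype(self.counts.dtype, np.integer):
                if np.any(self.counts != np.floor(self.counts)):
                    g, c = np.argwhere(self.counts != np.floor(self.counts))[0]
                    raise CountsValidationError(
                        f"non-integer count at gene {self.gene_ids[g]!r}, "
                        f"cell {self.cell_ids[c]!r}"
                    )
                self.counts = self.counts.astype(np.int64)
        meta = self.cell_meta
        if list(meta.index) != self.cell_ids:
            try:
                meta = meta.loc[self.cell_ids]
            except KeyError as exc:
                raise CountsValidationError(
                    f"cell_meta is missing records: {exc}"
                ) from exc
        for col in ("gate", "region", "source"):
            if col not in meta.columns:
                meta[col] = "" if col != "gate" else "other"
        meta = meta.copy()
        meta["gate"] = [_normalize_gate(g) for g in meta["gate"]]
        self.cell_meta = meta[["gate", "region", "source"]]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gates(self) -> np.ndarray:
        return self.cell_meta["gate"].to_numpy()

    def subset_cells(self, mask_or_ids) -> "CountsMatrix":
        if isinstance(mask_or_ids, (list, tuple)) and mask_or_ids and isinstance(
            mask_or_ids[0], str
        ):
            idx = [self.cell_ids.index(c) for c in mask_or_ids]
        else:
            idx = np.flatnonzero(np.asarray(mask_or_ids))
        cells = [self.cell_ids[i] for i in idx]
        return CountsMatrix(
            gene_ids=list(self.gene_ids),
            cell_ids=cells,
            counts=self.counts[:, idx],
            cell_meta=self.cell_meta.loc[cells].copy(),
        )


def default_cell_meta(cell_ids: list[str]) -> pd.DataFrame:
    return pd.DataFrame(
        {"gate": "other", "region": "", "source": ""},
        index=pd.Index([str(c) for c in cell_ids], name="cell_id"),
    )


@dataclass(frozen=True)
class DetectionSummary:
    """Per-cell detected-transcript counts and total assigned reads."""

    cell_ids: list[str]
    per_cell_detected: np.ndarray
    per_cell_total_reads: np.ndarray
    threshold: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "detected": self.per_cell_detected,
                "total_reads": self.per_cell_total_reads,
            },
            index=pd.Index(self.cell_ids, name="cell_id"),
        )


# ---------------------------------------------------------------------------
# sidecar path conventions


def _base(path: Path) -> Path:
    return path.with_suffix("") if path.suffix else path


def sidecar_paths(path) -> dict:
    """Sidecar file locations for a counts file at ``path``."""
    base = _base(Path(path))
    return {
        "genes": base.with_name(base.name + ".genes.txt"),
        "cells": base.with_name(base.name + ".cells.txt"),
        "meta": base.with_name(base.name + ".meta.tsv"),
    }


def _read_meta_sidecar(path, cell_ids: list[str]) -> pd.DataFrame:
    meta_path = sidecar_paths(path)["meta"]
    meta = default_cell_meta(cell_ids)
    if meta_path.exists():
        table = pd.read_csv(meta_path, sep="\t", dtype=str).fillna("")
        if "cell_id" not in table.columns:
            raise CountsFormatError(
                f"{meta_path}: metadata table lacks a cell_id column"
            )
        table = table.set_index("cell_id")
        common = [c for c in cell_ids if c in table.index]
        for col in ("gate", "region", "source"):
            if col in table.columns:
                meta.loc[common, col] = table.loc[common, col]
    return meta


def _write_meta_sidecar(m: CountsMatrix, path) -> None:
    meta_path = sidecar_paths(path)["meta"]
    out = m.cell_meta.copy()
    out.index.name = "cell_id"
    out.to_csv(meta_path, sep="\t")


# ---------------------------------------------------------------------------
# readers / writers


def read_counts(path, format: str = "dense-table") -> CountsMatrix:
    """Read a counts matrix in the named dialect.

    ``dense-table``: TSV, first column gene ids, header row of cell ids.
    ``sparse-triplet``: MatrixMarket coordinate file; gene and cell ids come
    from ``<base>.genes.txt`` / ``<base>.cells.txt`` sidecars (one id per
    line, genes file first dimension).  Per-cell metadata is read from an
    optional ``<base>.meta.tsv`` sidecar; absent cells default to
    gate="other".
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format.lower()
    if fmt in DENSE_FORMATS:
        gene_ids, cell_ids, counts = _read_dense(path)
    elif fmt in SPARSE_FORMATS:
        gene_ids, cell_ids, counts = _read_triplet(path)
    else:
        raise ValueError(f"unknown counts format {format!r}")
    meta = _read_meta_sidecar(path, cell_ids)
    try:
        return CountsMatrix(gene_ids, cell_ids, counts, meta)
    except CountsValidationError as exc:
        raise CountsValidationError(f"{path}: {exc}") from exc


def _read_dense(path: Path):
    if path.stat().st_size == 0:
        raise CountsFormatError(f"{path}: empty file")
    try:
        table = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pandas raises several parser error types
        raise CountsFormatError(f"{path}: {exc}") from exc
    if table.shape[1] == 0:
        raise CountsFormatError(f"{path}: header row has no cell columns")
    values = table.to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        bad = table.columns[
            [not np.issubdtype(d, np.number) for d in table.dtypes]
        ]
        raise CountsValidationError(
            f"{path}: non-numeric entries in column(s) {list(bad)}"
        )
    return (
        [str(g) for g in table.index],
        [str(c) for c in table.columns],
        values,
    )


def _read_triplet(path: Path):
    if path.stat().st_size == 0:
        raise CountsFormatError(f"{path}: empty file")
    try:
        mat = scipy.io.mmread(path)
    except Exception as exc:
        raise CountsFormatError(f"{path}: {exc}") from exc
    sc = sidecar_paths(path)
    for key in ("genes", "cells"):
        if not sc[key].exists():
            raise CountsFormatError(
                f"{path}: missing sidecar id file {sc[key]}"
            )
    gene_ids = sc["genes"].read_text().split()
    cell_ids = sc["cells"].read_text().split()
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
    if dense.shape != (len(gene_ids), len(cell_ids)):
        raise CountsFormatError(
            f"{path}: matrix shape {dense.shape} does not match sidecar ids "
            f"({len(gene_ids)} genes, {len(cell_ids)} cells)"
        )
    return gene_ids, cell_ids, dense


def write_counts(m: CountsMatrix, path, format: str = "dense-table") -> Path:
    """Write ``m`` so that :func:`read_counts` reproduces it exactly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fmt = format.lower()
    if fmt in DENSE_FORMATS:
        table = pd.DataFrame(
            m.counts, index=pd.Index(m.gene_ids, name="gene_id"),
            columns=m.cell_ids,
        )
        table.to_csv(path, sep="\t")
    elif fmt in SPARSE_FORMATS:
        coo = scipy.sparse.coo_matrix(m.counts.astype(np.int64))
        scipy.io.mmwrite(str(path), coo, field="integer")
        sc = sidecar_paths(path)
        sc["genes"].write_text("\n".join(m.gene_ids) + "\n")
        sc["cells"].write_text("\n".join(m.cell_ids) + "\n")
    else:
        raise ValueError(f"unknown counts format {format!r}")
    _write_meta_sidecar(m, path)
    return path


# ---------------------------------------------------------------------------
# detection summaries


def detection_summary(m: CountsMatrix, threshold: int = 1) -> DetectionSummary:
    """Count transcripts detected at >= ``threshold`` raw counts per cell.

    With the default threshold of 1 this is the per-column nonzero count,
    the quantity behind "transcripts detected per cell".
    """
    if threshold < 1:
        raise ValueError("detection threshold must be >= 1")
    detected = (m.counts >= threshold).sum(axis=0).astype(np.int64)
    totals = m.counts.sum(axis=0).astype(np.int64)
    return DetectionSummary(
        cell_ids=list(m.cell_ids),
        per_cell_detected=detected,
        per_cell_total_reads=totals,
        threshold=int(threshold),
    )


def detection_depth_correlation(s: DetectionSummary) -> float:
    """Pearson correlation between detected-transcript count and read depth.

    Used to check that differences in transcripts detected between cell
    classes are not driven by sequencing depth.
    """
    x = np.asarray(s.per_cell_detected, dtype=float)
    y = np.asarray(s.per_cell_total_reads, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 cells for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(
            "zero variance in detected counts or total reads"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r, _ = stats.pearsonr(x, y)
    return float(r)
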