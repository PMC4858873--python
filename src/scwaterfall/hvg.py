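"""Highly variable transcript selection by Winsorized mean-CV regression.

Technical noise in single-cell counts makes raw variance a poor gene-selection
statistic: the coefficient of variation (CV) falls with mean expression, so
genes must be judged against that trend rather than in absolute terms.  The
procedure here:

1. Winsorize each gene's normalized counts so its two most extreme cells
   cannot dominate (the top ``n_winsor`` values are replaced by the next
   largest value).
2. Compute per-gene mean and CV (unbiased SD / mean) of the Winsorized
   values and log2-transform both.
3. Fit an ordinary least-squares line of log2 CV on log2 mean, with a
   pointwise 95% confidence band for reporting.
4. Rank genes by the significance of their deviation from the line
   (standardized residual, descending).
5. Keep the top N ranked genes whose log2 mean exceeds a floor (default 3,
   i.e. mean normalized count > 8), which removes genes whose apparent
   variability is dropout-driven.

Ties in deviation score are broken by descending log mean, then gene id, so
selection is reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .normalization import NormalizedMatrix

logger = logging.getLogger(__name__)


def winsorize_gene(values, n_extreme: int = 2) -> np.ndarray:
    """Replace the ``n_extreme`` largest values with the next largest.

    Upper Winsorization only: the stated purpose is to stop a couple of
    extreme cells from inflating a gene's apparent variability, so the lower
    tail is untouched.  Idempotent for fixed ``n_extreme``.
    """
    values = np.asarray(values, dtype=float)
    if n_extreme < 0:
        raise ValueError("n_extreme must be non-negative")
    if n_extreme >= values.size:
        raise ValueError(
            f"n_extreme={n_extreme} must be smaller than the number of "
            f"cells ({values.size})"
        )
    if n_extreme == 0:
        return values.copy()
    out = values.copy()
    order = np.argsort(values, kind="stable")
    cap = values[order[-(n_extreme + 1)]]
    out[order[-n_extreme:]] = cap
    return out


@dataclass
class GeneStats:
    """Per-gene Winsorized mean/CV statistics on the log2 scale.

    ``table`` is indexed by gene id with columns mean, cv, log_mean, log_cv;
    genes whose Winsorized mean or CV is zero (log undefined) are excluded
    and listed in ``dropped``.
    """

    table: pd.DataFrame
    dropped: list[str] = field(default_factory=list)
    n_winsor: int = 2


def gene_stats(nm: NormalizedMatrix, n_winsor: int = 2) -> GeneStats:
    if nm.n_cells < 2:
        raise ValueError("CV is undefined with fewer than 2 cells")
    wins = np.apply_along_axis(winsorize_gene, 1, nm.norm_counts, n_winsor)
    means = wins.mean(axis=1)
    sds = wins.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cvs = np.where(means > 0, sds / np.where(means > 0, means, 1.0), np.nan)
    keep = (means > 0) & (cvs > 0)
    dropped = [g for g, k in zip(nm.gene_ids, keep) if not k]
    if dropped:
        logger.warning(
            "%d gene(s) dropped from mean-CV fit (zero mean or zero CV)",
            len(dropped),
        )
    table = pd.DataFrame(
        {
            "mean": means[keep],
            "cv": cvs[keep],
            "log_mean": np.log2(means[keep]),
            "log_cv": np.log2(cvs[keep]),
        },
        index=pd.Index(
            [g for g, k in zip(nm.gene_ids, keep) if k], name="gene_id"
        ),
    )
    return GeneStats(table=table, dropped=dropped, n_winsor=n_winsor)


@dataclass
class TrendFit:
    """OLS fit of log2 CV on log2 mean with a pointwise 95% band."""

    slope: float
    intercept: float
    resid_se: float
    n: int
    _model: object = None

    def predict(self, log_mean) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(log_mean, dtype=float)

    def confidence_band(self, log_mean) -> tuple[np.ndarray, np.ndarray]:
        """Pointwise 95% confidence interval of the fitted mean line."""
        x = np.asarray(log_mean, dtype=float)
        X = sm.add_constant(x, has_constant="add")
        pred = self._model.get_prediction(X)
        ci = pred.conf_int(alpha=0.05)
        return ci[:, 0], ci[:, 1]


def fit_mean_cv_trend(gs: GeneStats) -> TrendFit:
    tab = gs.table
    if len(tab) < 3:
        raise ValueError("need at least 3 genes to fit the mean-CV trend")
    x = tab["log_mean"].to_numpy()
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all log means equal")
    X = sm.add_constant(x)
    fit = sm.OLS(tab["log_cv"].to_numpy(), X).fit()
    resid_se = float(np.sqrt(fit.scale)) if fit.df_resid > 0 else 0.0
    return TrendFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        resid_se=resid_se,
        n=len(tab),
        _model=fit,
    )


def rank_variable_genes(gs: GeneStats, trend: TrendFit) -> pd.DataFrame:
    """Standardized residual from the trend, ranked descending.

    Rank 1 is the gene whose CV most significantly exceeds its
    mean-matched expectation.
    """
    tab = gs.table.copy()
    resid = tab["log_cv"].to_numpy() - trend.predict(tab["log_mean"])
    se = trend.resid_se if trend.resid_se > 0 else 1.0
    tab["residual"] = resid
    tab["deviation_score"] = resid / se
    order = tab.sort_values(
        by=["deviation_score", "log_mean", "gene_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).index
    tab["rank"] = pd.Series(
        np.arange(1, len(tab) + 1), index=order
    ).reindex(tab.index)
    return tab


def select_top_hvg(
    ranked: pd.DataFrame, n_top: int = 1000, mean_floor_log2: float = 3.0
) -> list[str]:
    """Top ``n_top`` ranked genes with log2 mean above the floor."""
    eligible = ranked[ranked["log_mean"] > mean_floor_log2]
    eligible = eligible.sort_values("rank")
    if len(eligible) < n_top:
        logger.warning(
            "only %d genes pass the mean floor (requested %d)",
            len(eligible),
            n_top,
        )
    return list(eligible.index[:n_top])


@dataclass
class HvgResult:
    """Full record of a highly-variable-gene selection."""

    trend: TrendFit
    table: pd.DataFrame
    selected: list[str]
    dropped: list[str]
    parameters: dict

    def export(self, path) -> Path:
        path = Path(path)
        out = self.table.copy()
        out["selected"] = out.index.isin(set(self.selected)).astype(int)
        out = out[
            ["mean", "cv", "log_mean", "log_cv", "deviation_score", "rank",
             "selected"]
        ]
        out.to_csv(path, sep="\t", float_format="%.10g")
        return path


def select_hvgs(
    nm: NormalizedMatrix,
    n_top: int = 1000,
    mean_floor_log2: float = 3.0,
    n_winsor: int = 2,
) -> HvgResult:
    """Run the full Winsorize -> mean/CV -> trend -> rank -> floor pipeline."""
    gs = gene_stats(nm, n_winsor=n_winsor)
    trend = fit_mean_cv_trend(gs)
    ranked = rank_variable_genes(gs, trend)
    selected = select_top_hvg(ranked, n_top=n_top, mean_floor_log2=mean_floor_log2)
    return HvgResult(
        trend=trend,
        table=ranked,
        selected=selected,
        dropped=gs.dropped,
        parameters={
            "n_top": n_top,
            "mean_floor_log2": mean_floor_log2,
            "n_winsor": n_winsor,
        },
    )
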