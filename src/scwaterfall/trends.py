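"""Gene-expression trends over pseudotime by local polynomial regression.

For each gene, expression is smoothed against pseudotime with a degree-2
local polynomial (loess-style): at each grid point the nearest span-fraction
of cells is weighted by the tricube kernel and a weighted quadratic is
fitted; the fitted value is the local intercept.  The pointwise 95% band
comes from the sampling variance of that local linear smoother,
var(fhat(x)) = sigma^2 * ||l(x)||^2, with sigma^2 estimated from the
residuals at the observed points.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats


@dataclass
class GeneTrend:
    """Fitted mean curve with pointwise 95% confidence band."""

    grid: np.ndarray
    fit: np.ndarray
    lower95: np.ndarray
    upper95: np.ndarray
    span: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("evaluation grid must be strictly increasing")
        if np.any(self.upper95 < self.fit - 1e-9) or np.any(
            self.lower95 > self.fit + 1e-9
        ):
            raise ValueError("band must bracket the fitted curve")

    def export(self, path) -> Path:
        path = Path(path)
        pd.DataFrame(
            {
                "grid_t": self.grid,
                "fit": self.fit,
                "lower95": self.lower95,
                "upper95": self.upper95,
            }
        ).to_csv(path, sep="\t", index=False, float_format="%.10g")
        return path


def _local_fit(x, y, x0, h, degree):
    """Weighted polynomial fit at x0; returns (fitted value, ||l(x0)||^2)."""
    d = np.abs(x - x0)
    if h <= 0:
        h = np.finfo(float).eps
    u = np.clip(d / h, 0.0, 1.0)
    w = (1.0 - u**3) ** 3
    active = w > 0
    if active.sum() < degree + 1:
        # widen to the nearest degree+1 points with uniform weights
        idx = np.argsort(d, kind="stable")[: degree + 1]
        active = np.zeros_like(w, dtype=bool)
        active[idx] = True
        w = np.where(active, 1.0, 0.0)
    xa, ya, wa = x[active], y[active], w[active]
    # design centered at x0 so the intercept is the fitted value
    X = np.vander(xa - x0, N=degree + 1, increasing=True)
    WX = X * wa[:, None]
    A = X.T @ WX
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        Ainv = np.linalg.pinv(A)
    lvec = (Ainv[0] @ (WX.T))  # row of the smoother matrix (active part)
    return float(lvec @ ya), float(lvec @ lvec)


def gene_trend(
    pt: np.ndarray,
    expr: np.ndarray,
    span: float = 0.75,
    degree: int = 2,
    n_grid: int = 100,
) -> GeneTrend:
    """Fit a smooth expression trend over pseudotime.

    ``span`` is the fraction of cells entering each local fit; the kernel
    bandwidth at a grid point is the distance to the ceil(span*n)-th nearest
    cell.  Requires at least 10 cells and non-constant pseudotime.
    """
    pt = np.asarray(pt, dtype=float)
    expr = np.asarray(expr, dtype=float)
    if pt.shape != expr.shape:
        raise ValueError("pseudotime and expression must have equal length")
    n = pt.size
    if n < 10:
        raise ValueError("need at least 10 cells to fit a trend")
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    if np.ptp(pt) == 0:
        raise ValueError("all pseudotime values identical; trend undefined")
    k = max(degree + 2, int(np.ceil(span * n)))
    k = min(k, n)
    grid = np.linspace(pt.min(), pt.max(), n_grid)

    fits = np.empty(n_grid)
    lnorms = np.empty(n_grid)
    for i, x0 in enumerate(grid):
        d = np.abs(pt - x0)
        h = np.partition(d, k - 1)[k - 1]
        fits[i], lnorms[i] = _local_fit(pt, expr, x0, h, degree)

    # residual variance from leave-in fits at the observed points
    fitted_at_obs = np.empty(n)
    for i, x0 in enumerate(pt):
        d = np.abs(pt - x0)
        h = np.partition(d, k - 1)[k - 1]
        fitted_at_obs[i], _ = _local_fit(pt, expr, x0, h, degree)
    dof = max(n - (degree + 1), 1)
    sigma2 = float(np.sum((expr - fitted_at_obs) ** 2) / dof)
    tcrit = sstats.t.ppf(0.975, dof)
    half = tcrit * np.sqrt(sigma2 * lnorms)
    return GeneTrend(
        grid=grid,
        fit=fits,
        lower95=fits - half,
        upper95=fits + half,
        span=span,
    )
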