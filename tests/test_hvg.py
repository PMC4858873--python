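"""Winsorized mean-CV regression and highly-variable-gene ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scwaterfall import CountsMatrix, normalize, select_hvgs, winsorize_gene
from scwaterfall.hvg import (
    GeneStats,
    fit_mean_cv_trend,
    gene_stats,
    rank_variable_genes,
    select_top_hvg,
)


class TestWinsorize:
    @pytest.mark.parametrize(
        "values,n,expected",
        [
            ([1, 2, 3, 100, 200], 2, [1, 2, 3, 3, 3]),
            ([5, 5, 5, 5], 2, [5, 5, 5, 5]),
            ([7, 1, 9], 1, [7, 1, 7]),
        ],
    )
    def test_caps_largest_values(self, values, n, expected):
        np.testing.assert_array_equal(
            winsorize_gene(values, n), np.asarray(expected, dtype=float)
        )

    def test_zero_extreme_is_identity(self):
        v = np.array([3.0, 1.0, 4.0])
        np.testing.assert_array_equal(winsorize_gene(v, 0), v)

    def test_too_many_extremes_rejected(self):
        with pytest.raises(ValueError, match="n_extreme"):
            winsorize_gene([1, 2, 3], 3)

    @given(
        st.lists(st.floats(0, 1e6), min_size=4, max_size=20),
        st.integers(0, 3),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_idempotent(self, values, n):
        once = winsorize_gene(values, n)
        twice = winsorize_gene(once, n)
        np.testing.assert_array_equal(once, twice)


class TestGeneStats:
    def test_hand_computed_mean_and_cv(self, random_normalized):
        nm = random_normalized(n_genes=1, n_cells=2)
        nm.norm_counts[0] = [2.0, 4.0]
        gs = gene_stats(nm, n_winsor=0)
        assert gs.table.loc["g000", "mean"] == pytest.approx(3.0)
        assert gs.table.loc["g000", "cv"] == pytest.approx(np.sqrt(2) / 3)

    def test_constant_gene_dropped_with_record(self, random_normalized):
        nm = random_normalized(n_genes=3, n_cells=5)
        nm.norm_counts[1] = 4.0  # cv = 0, log undefined
        gs = gene_stats(nm, n_winsor=0)
        assert "g001" in gs.dropped
        assert "g001" not in gs.table.index

    def test_single_cell_rejected(self, random_normalized):
        nm = random_normalized(n_cells=1)
        with pytest.raises(ValueError, match="2 cells"):
            gene_stats(nm)

    def test_cv_scale_invariance(self, random_normalized):
        nm = random_normalized(n_genes=10, n_cells=8, seed=5)
        base = gene_stats(nm, n_winsor=2)
        nm.norm_counts *= 3.0
        scaled = gene_stats(nm, n_winsor=2)
        np.testing.assert_allclose(
            scaled.table["cv"], base.table["cv"], rtol=1e-12
        )
        np.testing.assert_allclose(
            scaled.table["mean"], base.table["mean"] * 3, rtol=1e-12
        )


class TestTrendFit:
    def test_exact_line_has_zero_residual_error(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        gs = _stats_from(log_mean=x, log_cv=2 * x + 1)
        trend = fit_mean_cv_trend(gs)
        assert trend.slope == pytest.approx(2.0)
        assert trend.intercept == pytest.approx(1.0)
        assert trend.resid_se == pytest.approx(0.0, abs=1e-10)

    def test_hand_ols_four_points(self):
        # OLS of y=(0,1,1,2) on x=(0,1,2,3): slope 0.6, intercept 0.1
        gs = _stats_from(log_mean=[0, 1, 2, 3], log_cv=[0, 1, 1, 2])
        trend = fit_mean_cv_trend(gs)
        assert trend.slope == pytest.approx(0.6)
        assert trend.intercept == pytest.approx(0.1)

    def test_confidence_band_narrowest_at_mean_x(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        y = 1.5 * x + rng.normal(scale=0.3, size=40)
        trend = fit_mean_cv_trend(_stats_from(x, y))
        grid = np.array([x.mean() - 2, x.mean(), x.mean() + 2])
        lo, hi = trend.confidence_band(grid)
        widths = hi - lo
        assert widths[1] < widths[0] and widths[1] < widths[2]

    def test_degenerate_design_rejected(self):
        gs = _stats_from(log_mean=[1, 1, 1], log_cv=[0, 1, 2])
        with pytest.raises(ValueError, match="degenerate"):
            fit_mean_cv_trend(gs)


class TestRankingAndSelection:
    def test_higher_cv_at_equal_mean_ranks_first(self):
        gs = _stats_from(
            log_mean=[0, 1, 2, 1], log_cv=[0, 0.5, 1, 1.5],
            ids=["a", "b", "c", "d"],
        )
        ranked = rank_variable_genes(gs, fit_mean_cv_trend(gs))
        assert ranked.loc["d", "rank"] < ranked.loc["b", "rank"]

    def test_on_line_gene_scores_zero(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 1.5])
        y = 0.5 * x - 1
        # noise orthogonal to (1, x): leaves the OLS line unchanged
        y[:4] += np.array([0.2, -0.2, -0.2, 0.2])
        gs = _stats_from(x, y, ids=list("abcde"))
        ranked = rank_variable_genes(gs, fit_mean_cv_trend(gs))
        assert ranked.loc["e", "deviation_score"] == pytest.approx(0.0, abs=1e-9)

    def test_ranking_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(0, 8, size=20)
        y = -0.4 * x + rng.normal(scale=0.5, size=20)
        ids = [f"g{i:02d}" for i in range(20)]
        gs = _stats_from(x, y, ids=ids)
        ranked = rank_variable_genes(gs, fit_mean_cv_trend(gs))
        # straight-line re-implementation with closed-form OLS
        xm, ym = x.mean(), y.mean()
        slope = np.sum((x - xm) * (y - ym)) / np.sum((x - xm) ** 2)
        intercept = ym - slope * xm
        resid = y - (intercept + slope * x)
        se = np.sqrt(np.sum(resid**2) / (20 - 2))
        oracle_order = [
            ids[i] for i in np.argsort(-(resid / se), kind="stable")
        ]
        assert list(ranked.sort_values("rank").index) == oracle_order

    def test_mean_floor_excludes_top_ranked_gene(self):
        gs = _stats_from(
            log_mean=[2.9, 4, 5, 6], log_cv=[5, 0.1, 0.0, -0.1],
            ids=["low", "a", "b", "c"],
        )
        ranked = rank_variable_genes(gs, fit_mean_cv_trend(gs))
        assert ranked.loc["low", "rank"] == 1
        selected = select_top_hvg(ranked, n_top=2, mean_floor_log2=3.0)
        assert "low" not in selected and len(selected) == 2

    def test_fewer_eligible_than_requested_returns_all(self):
        gs = _stats_from([4, 5, 6], [0.1, 0.3, -0.2], ids=list("abc"))
        ranked = rank_variable_genes(gs, fit_mean_cv_trend(gs))
        assert len(select_top_hvg(ranked, n_top=10, mean_floor_log2=3.0)) == 3

    def test_ten_gene_toy_selection_by_hand(self):
        # ranks follow deviation scores; floor keeps log_mean > 3 only
        x = np.array([1, 2, 3.5, 4, 4.5, 5, 5.5, 6, 6.5, 7.0])
        dev = np.array([9, 8, 7, 6, 5, -1, -2, -3, -4, -5.0])
        ids = [f"g{i}" for i in range(10)]
        gs = _stats_from(x, dev, ids=ids)  # steeply decreasing => g0 top
        ranked = rank_variable_genes(gs, fit_mean_cv_trend(gs))
        selected = select_top_hvg(ranked, n_top=4, mean_floor_log2=3.0)
        eligible = [i for i, xi in zip(ids, x) if xi > 3.0]
        expected = sorted(
            eligible, key=lambda g: ranked.loc[g, "rank"]
        )[:4]
        assert selected == expected


class TestFullSelectionOracle:
    def test_matches_independent_reimplementation(self, random_normalized):
        nm = random_normalized(n_genes=50, n_cells=20, seed=7)
        res = select_hvgs(nm, n_top=15, mean_floor_log2=-10, n_winsor=2)

        # independent straight-line pipeline
        wins = nm.norm_counts.copy()
        for gi in range(50):
            order = np.argsort(wins[gi])
            cap = wins[gi][order[-3]]
            wins[gi][order[-2:]] = cap
        means = wins.mean(axis=1)
        sds = wins.std(axis=1, ddof=1)
        cv = sds / means
        lm, lc = np.log2(means), np.log2(cv)
        slope = np.sum((lm - lm.mean()) * (lc - lc.mean())) / np.sum(
            (lm - lm.mean()) ** 2
        )
        inter = lc.mean() - slope * lm.mean()
        resid = lc - (inter + slope * lm)
        se = np.sqrt(np.sum(resid**2) / (50 - 2))
        score = resid / se
        order = np.lexsort((nm.gene_ids, -lm, -score))
        expected = [nm.gene_ids[i] for i in order[:15]]
        assert res.selected == expected

    def test_deviation_scores_invariant_to_global_scaling(
        self, random_normalized
    ):
        nm = random_normalized(n_genes=30, n_cells=10, seed=2)
        base = select_hvgs(nm, n_top=5, mean_floor_log2=-10)
        nm2 = random_normalized(n_genes=30, n_cells=10, seed=2)
        nm2.norm_counts *= 4.0
        scaled = select_hvgs(nm2, n_top=5, mean_floor_log2=-10)
        np.testing.assert_allclose(
            scaled.table["deviation_score"],
            base.table["deviation_score"],
            atol=1e-9,
        )
        assert scaled.selected == base.selected

    def test_report_export_columns(self, random_normalized, tmp_path):
        nm = random_normalized()
        res = select_hvgs(nm, n_top=5, mean_floor_log2=-10)
        path = res.export(tmp_path / "hvg.tsv")
        back = pd.read_csv(path, sep="\t", index_col="gene_id")
        assert list(back.columns) == [
            "mean", "cv", "log_mean", "log_cv", "deviation_score", "rank",
            "selected",
        ]
        assert back["selected"].sum() == 5


def _stats_from(log_mean, log_cv, ids=None):
    log_mean = np.asarray(log_mean, dtype=float)
    log_cv = np.asarray(log_cv, dtype=float)
    if ids is None:
        ids = [f"g{i}" for i in range(len(log_mean))]
    table = pd.DataFrame(
        {
            "mean": 2.0**log_mean,
            "cv": 2.0**log_cv,
            "log_mean": log_mean,
            "log_cv": log_cv,
        },
        index=pd.Index(ids, name="gene_id"),
    )
    return GeneStats(table=table, dropped=[], n_winsor=0)
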