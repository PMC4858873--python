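"""Trajectory core: PCA, k-means centers, MST, linearization, pseudotime."""

import itertools

import numpy as np
import pytest

from scwaterfall import (
    TrajectoryGraph,
    assign_pseudotime,
    kmeans_centers,
    linearize,
    mst,
    orient,
    pca,
)
from scwaterfall.waterfall import OrientationError


class TestPca:
    def test_collinear_points_have_single_component(self):
        t = np.linspace(0, 1, 8)
        x = np.column_stack([t, 2 * t, -t])
        res = pca(x, n_pcs=2)
        assert res.variance_explained[0] == pytest.approx(1.0)
        assert res.variance_explained[1] == pytest.approx(0.0, abs=1e-12)

    def test_scores_reconstruct_centered_data_at_full_rank(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(10, 4))
        res = pca(x, n_pcs=4)
        np.testing.assert_allclose(
            res.scores @ res.loadings.T + res.center, x, atol=1e-10
        )

    def test_hand_svd_diagonal_line(self):
        x = np.array([[0, 0], [1, 1], [2, 2], [3, 3]], dtype=float)
        res = pca(x, n_pcs=1)
        np.testing.assert_allclose(
            res.loadings[:, 0], [1 / np.sqrt(2), 1 / np.sqrt(2)]
        )
        s = np.sqrt(2)
        np.testing.assert_allclose(
            res.scores[:, 0], [-3 * s / 2, -s / 2, s / 2, 3 * s / 2]
        )

    def test_loadings_orthonormal_and_sign_convention(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(15, 6))
        res = pca(x, n_pcs=3)
        np.testing.assert_allclose(
            res.loadings.T @ res.loadings, np.eye(3), atol=1e-10
        )
        for j in range(3):
            assert res.loadings[np.argmax(np.abs(res.loadings[:, j])), j] > 0

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pca(np.ones((5, 3)), n_pcs=1)

    def test_too_many_pcs_rejected(self):
        with pytest.raises(ValueError, match="n_pcs"):
            pca(np.random.default_rng(0).normal(size=(3, 5)), n_pcs=3)


class TestKmeans:
    def test_k_equals_n_zero_inertia(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(5, 2))
        centers, assign = kmeans_centers(pts, k=5, seed=0)
        # every point is its own center
        d = np.linalg.norm(pts - centers[assign], axis=1)
        np.testing.assert_allclose(d, 0, atol=1e-12)

    def test_two_blobs_recovered(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(10, 2)) * 0.1
        b = rng.normal(size=(10, 2)) * 0.1 + 20
        pts = np.vstack([a, b])
        centers, assign = kmeans_centers(pts, k=2, seed=0)
        assert len(set(assign[:10])) == 1 and len(set(assign[10:])) == 1
        assert assign[0] != assign[10]

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(30, 2))
        c1, a1 = kmeans_centers(pts, k=4, seed=9)
        c2, a2 = kmeans_centers(pts, k=4, seed=9)
        np.testing.assert_array_equal(c1, c2)
        np.testing.assert_array_equal(a1, a2)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_centers(np.zeros((3, 2)), k=4)


def _bruteforce_mst_weight(centers):
    """Minimum total weight over all spanning trees (Cayley enumeration)."""
    k = len(centers)
    d = np.linalg.norm(centers[:, None] - centers[None, :], axis=2)
    all_edges = [(i, j) for i in range(k) for j in range(i + 1, k)]
    best = np.inf
    for combo in itertools.combinations(all_edges, k - 1):
        parent = list(range(k))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        ok = True
        for i, j in combo:
            ri, rj = find(i), find(j)
            if ri == rj:
                ok = False
                break
            parent[ri] = rj
        if ok:
            best = min(best, sum(d[i, j] for i, j in combo))
    return best


class TestMst:
    def test_collinear_chain(self):
        centers = np.array([[0.0], [1.0], [5.0]])
        edges = mst(centers)
        assert [(i, j) for i, j, _ in edges] == [(0, 1), (1, 2)]

    def test_two_centers_single_edge(self):
        edges = mst(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert len(edges) == 1 and edges[0][2] == pytest.approx(5.0)

    def test_duplicate_centers_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            mst(np.array([[1.0, 2.0], [1.0, 2.0]]))

    @pytest.mark.parametrize("k", [4, 5, 6, 7])
    def test_weight_matches_bruteforce_enumeration(self, k):
        rng = np.random.default_rng(k)
        centers = rng.normal(size=(k, 2))
        edges = mst(centers)
        total = sum(w for _, _, w in edges)
        assert total == pytest.approx(_bruteforce_mst_weight(centers))


class TestLinearize:
    def test_path_tree_returned_verbatim(self):
        edges = [(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0)]
        path, off = linearize(edges)
        assert path in ([0, 1, 2, 3], [3, 2, 1, 0])
        assert off == []

    def test_star_tree_emits_branching_warning(self):
        edges = [(0, 1, 1.0), (0, 2, 2.0), (0, 3, 3.0)]
        path, off = linearize(edges)
        assert set(path) == {2, 0, 3}  # two longest arms
        assert off == [1]

    def test_y_tree_with_endpoints(self):
        #   0-1-2 with branches 2-3 and 2-4
        edges = [(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0), (2, 4, 1.0)]
        path, off = linearize(edges, endpoints=(0, 4))
        assert path == [0, 1, 2, 4]
        assert off == [3]

    def test_unknown_endpoint_rejected(self):
        with pytest.raises(ValueError, match="endpoints"):
            linearize([(0, 1, 1.0)], endpoints=(0, 9))


class TestOrient:
    def _setup(self):
        path = [0, 1, 2]
        assignment = np.array([0, 0, 1, 2, 2])
        stem = np.array([5.0, 5.0, 3.0, 1.0, 1.0])
        return path, assignment, stem

    def test_root_is_high_stem_end(self):
        path, assignment, stem = self._setup()
        oriented, warns = orient(list(reversed(path)), assignment, stem)
        assert oriented[0] == 0 and warns == []

    def test_agreeing_lineage_markers_no_warning(self):
        path, assignment, stem = self._setup()
        lineage = 10 - stem
        oriented, warns = orient(path, assignment, stem, lineage)
        assert oriented[0] == 0 and warns == []

    def test_conflicting_lineage_markers_warn_but_keep_stem_decision(self):
        path, assignment, stem = self._setup()
        lineage = stem.copy()  # conflicts: high at the stem end too
        oriented, warns = orient(path, assignment, stem, lineage)
        assert oriented[0] == 0
        assert warns and warns[0]["kind"] == "orientation-conflict"

    def test_tied_scores_demand_endpoints(self):
        path, assignment, _ = self._setup()
        with pytest.raises(OrientationError, match="tie"):
            orient(path, assignment, np.ones(5))


class TestPseudotime:
    def _graph(self):
        centers = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        return TrajectoryGraph(
            centers=centers,
            mst_edges=[(0, 1, 1.0), (1, 2, 1.0)],
            path=[0, 1, 2],
        )

    def test_on_path_cell_exact_arc_fraction(self):
        pt = assign_pseudotime(np.array([[0.5, 0.0]]), self._graph())
        assert pt.pseudotime[0] == pytest.approx(0.25)
        assert pt.projection_residual[0] == pytest.approx(0.0)

    def test_cell_beyond_root_clamps_to_zero(self):
        pt = assign_pseudotime(np.array([[-1.0, 0.0]]), self._graph())
        assert pt.pseudotime[0] == 0.0

    def test_offset_cell_residuals_by_hand(self):
        pt = assign_pseudotime(np.array([[0.5, 0.3]]), self._graph())
        assert pt.pseudotime[0] == pytest.approx(0.25)
        assert pt.projection_residual[0] == pytest.approx(0.3)
        # nearest center is (0,0) or (1,0), both at sqrt(0.25 + 0.09)
        assert pt.residual_distance[0] == pytest.approx(
            np.sqrt(0.5**2 + 0.3**2)
        )

    def test_rotation_invariance(self):
        rng = np.random.default_rng(6)
        cells = rng.normal(size=(20, 2)) + [1.0, 0.0]
        g = self._graph()
        base = assign_pseudotime(cells, g)
        theta = 0.7
        R = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        g_rot = TrajectoryGraph(
            centers=g.centers @ R.T, mst_edges=g.mst_edges, path=g.path
        )
        rot = assign_pseudotime(cells @ R.T, g_rot)
        np.testing.assert_allclose(rot.pseudotime, base.pseudotime, atol=1e-12)
        np.testing.assert_allclose(
            rot.residual_distance, base.residual_distance, atol=1e-12
        )

    def test_reversed_orientation_maps_t_to_one_minus_t(self):
        rng = np.random.default_rng(7)
        cells = rng.uniform(-0.2, 2.2, size=(25, 2))
        g = self._graph()
        fwd = assign_pseudotime(cells, g)
        g_rev = TrajectoryGraph(
            centers=g.centers, mst_edges=g.mst_edges, path=[2, 1, 0]
        )
        rev = assign_pseudotime(cells, g_rev)
        np.testing.assert_allclose(
            rev.pseudotime, 1.0 - fwd.pseudotime, atol=1e-12
        )

    def test_moving_toward_nearest_center_never_increases_residual(self):
        rng = np.random.default_rng(8)
        g = self._graph()
        cells = rng.normal(size=(10, 2)) * 2
        base = assign_pseudotime(cells, g)
        nearest = g.centers[base.center_assignment]
        moved = cells + 0.5 * (nearest - cells)
        after = assign_pseudotime(moved, g)
        assert np.all(
            after.residual_distance <= base.residual_distance + 1e-12
        )

    def test_degenerate_polyline_rejected(self):
        with pytest.raises(ValueError):
            TrajectoryGraph(
                centers=np.array([[0.0, 0.0]]),
                mst_edges=[],
                path=[0, 0],
            )
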