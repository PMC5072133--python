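"""PCA, convex hulls and overlap, dissimilarity matrices, Mantel tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import perivar as pv
from perivar.errors import DegenerateHullError, ValidationError
from perivar.community import DistanceMatrix, point_in_hull
from _oracles import exhaustive_mantel, hull_vertices_bruteforce
from conftest import long_table


class TestPca:
    def test_rank_one_data_loads_on_pc1(self):
        t = np.linspace(0, 1, 20)
        M = np.outer(t, [1.0, 2.0, -0.5]) + 3.0
        res = pv.pca(M)
        assert res.var_explained[0] == pytest.approx(100.0, abs=1e-8)

    def test_two_by_two_closed_form(self):
        rng = np.random.default_rng(0)
        M = rng.normal(size=(50, 2)) @ np.array([[1.0, 0.4], [0.0, 0.8]])
        res = pv.pca(M)
        C = np.cov(M.T)
        tr, det = C.trace(), np.linalg.det(C)
        roots = np.array(
            [(tr + np.sqrt(tr**2 - 4 * det)) / 2, (tr - np.sqrt(tr**2 - 4 * det)) / 2]
        )
        eig = res.var_explained / 100 * tr
        assert np.allclose(eig, roots, atol=1e-10)

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(1)
        M = rng.random((15, 6))
        res = pv.pca(M)
        assert np.abs(res.reconstruct() - M).max() < 1e-8

    def test_scores_orthogonal_and_variance_ordered(self):
        rng = np.random.default_rng(2)
        M = rng.random((30, 5))
        res = pv.pca(M)
        S = res.scores.to_numpy()
        G = S.T @ S
        assert np.abs(G - np.diag(np.diag(G))).max() < 1e-8
        assert (np.diff(res.var_explained) <= 1e-9).all()
        assert res.var_explained.sum() <= 100 + 1e-6

    def test_sign_convention_dominant_loading_positive(self):
        rng = np.random.default_rng(3)
        M = rng.random((25, 4))
        res = pv.pca(M)
        L = res.loadings.to_numpy()
        for j in range(L.shape[1]):
            assert L[np.argmax(np.abs(L[:, j])), j] > 0

    def test_agrees_with_sklearn(self):
        skd = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(4)
        M = rng.random((40, 6))
        res = pv.pca(M)
        sk = skd.PCA().fit(M)
        assert np.allclose(
            res.var_explained, 100 * sk.explained_variance_ratio_, atol=1e-8
        )

    def test_constant_matrix_raises(self):
        with pytest.raises(ValidationError):
            pv.pca(np.ones((5, 3)))


class TestConvexHull:
    def test_triangle_keeps_all_vertices(self):
        h = pv.convex_hull([(0, 0), (1, 0), (0, 1)])
        assert h.vertices.shape == (3, 2)

    def test_interior_point_excluded(self):
        h = pv.convex_hull([(0, 0), (1, 0), (1, 1), (0, 1), (0.5, 0.5)])
        assert h.vertices.shape == (4, 2)
        assert point_in_hull((0.5, 0.5), h)

    def test_counter_clockwise_orientation(self):
        h = pv.convex_hull([(0, 0), (2, 0), (2, 2), (0, 2)])
        v = h.vertices
        area2 = np.sum(v[:, 0] * np.roll(v[:, 1], -1) - np.roll(v[:, 0], -1) * v[:, 1])
        assert area2 > 0

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            pts = rng.random((12, 2))
            h = pv.convex_hull(pts)
            got = {tuple(np.round(v, 12)) for v in h.vertices}
            assert got == hull_vertices_bruteforce(pts)

    def test_matches_scipy(self):
        spatial = pytest.importorskip("scipy.spatial")
        rng = np.random.default_rng(6)
        pts = rng.random((30, 2))
        h = pv.convex_hull(pts)
        sp = spatial.ConvexHull(pts)
        got = {tuple(np.round(v, 12)) for v in h.vertices}
        want = {tuple(np.round(pts[i], 12)) for i in sp.vertices}
        assert got == want

    def test_collinear_raises_with_segment(self):
        with pytest.raises(DegenerateHullError) as exc:
            pv.convex_hull([(0, 0), (1, 1), (2, 2), (3, 3)])
        assert exc.value.points is not None

    def test_too_few_points(self):
        with pytest.raises(DegenerateHullError):
            pv.convex_hull([(0, 0), (1, 1)])

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.integers(0, 2**31 - 1))
    def test_every_point_inside_own_hull(self, seed):
        pts = np.random.default_rng(seed).random((15, 2))
        h = pv.convex_hull(pts)
        assert all(point_in_hull(p, h) for p in pts)


class TestHullOverlap:
    square = [(0, 0), (1, 0), (1, 1), (0, 1)]

    def test_identical_hulls(self):
        a = pv.convex_hull(self.square)
        rec = pv.hull_overlap(a, pv.convex_hull(self.square))
        assert rec["overlaps"] and rec["fraction_of_b_points_inside_a"] == 1.0

    def test_disjoint_squares(self):
        a = pv.convex_hull(self.square)
        b = pv.convex_hull([(x + 10, y) for x, y in self.square])
        rec = pv.hull_overlap(a, b)
        assert not rec["overlaps"] and rec["fraction_of_b_points_inside_a"] == 0.0

    def test_cross_shape_edge_only_intersection(self):
        # tall thin rectangle x wide flat rectangle: no vertex containment
        a = pv.convex_hull([(-0.1, -1), (0.1, -1), (0.1, 1), (-0.1, 1)])
        b = pv.convex_hull([(-1, -0.1), (1, -0.1), (1, 0.1), (-1, 0.1)])
        rec = pv.hull_overlap(a, b)
        assert rec["overlaps"]
        assert rec["fraction_of_b_points_inside_a"] == 0.0

    def test_agrees_with_shapely(self):
        shapely = pytest.importorskip("shapely.geometry")
        rng = np.random.default_rng(7)
        for _ in range(20):
            pa = rng.random((8, 2))
            pb = rng.random((8, 2)) + rng.uniform(-0.8, 0.8, 2)
            a, b = pv.convex_hull(pa), pv.convex_hull(pb)
            got = pv.hull_overlap(a, b)["overlaps"]
            want = shapely.MultiPoint(list(map(tuple, pa))).convex_hull.intersects(
                shapely.MultiPoint(list(map(tuple, pb))).convex_hull
            )
            assert got == want


class TestDistanceMatrix:
    toy = long_table(
        {
            "s1": {"a": 4.0, "b": 0.0, "c": 4.0},
            "s2": {"a": 1.0, "b": 1.0, "c": 0.0},
            "s3": {"a": 0.0, "b": 3.0, "c": 0.0},
        }
    )

    def test_identical_slides_distance_zero(self):
        tab = long_table({"s1": {"a": 1, "b": 2}, "s2": {"a": 1, "b": 2}})
        for m in ("sorensen", "euclidean", "bray_curtis"):
            assert pv.distance_matrix(tab, m).values.iloc[0, 1] == pytest.approx(0.0)

    def test_disjoint_presence_sets(self):
        tab = long_table({"s1": {"a": 2, "b": 0}, "s2": {"a": 0, "b": 5}})
        assert pv.distance_matrix(tab, "sorensen").values.iloc[0, 1] == 1.0
        assert pv.distance_matrix(tab, "bray_curtis").values.iloc[0, 1] == 1.0

    def test_hand_computed_toy(self):
        # presence: s1={a,c}, s2={a,b}, s3={b}
        sor = pv.distance_matrix(self.toy, "sorensen").values
        assert sor.loc["s1", "s2"] == pytest.approx(1 - 2 * 1 / (2 * 1 + 1 + 1))
        assert sor.loc["s1", "s3"] == pytest.approx(1.0)
        assert sor.loc["s2", "s3"] == pytest.approx(1 - 2 * 1 / (2 * 1 + 1 + 0))
        # proportions: s1=(.5,0,.5), s2=(.5,.5,0), s3=(0,1,0)
        bc = pv.distance_matrix(self.toy, "bray_curtis").values
        assert bc.loc["s1", "s2"] == pytest.approx((0 + 0.5 + 0.5) / 2)
        assert bc.loc["s1", "s3"] == pytest.approx(1.0)
        eu = pv.distance_matrix(self.toy, "euclidean").values
        assert eu.loc["s1", "s2"] == pytest.approx(np.sqrt(0.25 + 0.25))

    def test_metric_axioms_on_random_table(self):
        rng = np.random.default_rng(8)
        tab = long_table(
            {f"s{i}": {f"t{j}": float(rng.random() > 0.3) * rng.random() + 1e-6 for j in range(6)} for i in range(8)}
        )
        for m in ("sorensen", "euclidean", "bray_curtis"):
            D = pv.distance_matrix(tab, m).values.to_numpy()
            assert np.allclose(D, D.T)
            assert np.allclose(np.diag(D), 0)
            assert (D >= 0).all()
            if m != "euclidean":
                assert (D <= 1 + 1e-12).all()
        E = pv.distance_matrix(tab, "euclidean").values.to_numpy()
        n = E.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert E[i, j] <= E[i, k] + E[k, j] + 1e-12

    def test_all_zero_slide_rejected(self):
        tab = long_table({"s1": {"a": 0.0}, "s2": {"a": 1.0}})
        with pytest.raises(ValidationError, match="s1"):
            pv.distance_matrix(tab, "bray_curtis")

    def test_unknown_metric(self):
        with pytest.raises(ValidationError):
            pv.distance_matrix(self.toy, "jaccard")


def _dm(M, ids):
    return DistanceMatrix(values=pd.DataFrame(M, index=ids, columns=ids), metric="euclidean")


class TestMantel:
    @staticmethod
    def random_dm(n, seed):
        rng = np.random.default_rng(seed)
        pts = rng.random((n, 2))
        D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        return _dm(D, [f"s{i}" for i in range(n)])

    def test_self_correlation_is_one(self):
        d = self.random_dm(8, 0)
        assert pv.mantel(d, d, n_perm=9, seed=0)["r"] == pytest.approx(1.0)

    def test_affine_invariance(self):
        d1 = self.random_dm(8, 1)
        M2 = 2.0 * d1.values.to_numpy() + 3.0
        np.fill_diagonal(M2, 0.0)
        d2 = _dm(M2, list(d1.values.index))
        assert pv.mantel(d1, d2, n_perm=9, seed=0)["r"] == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        d1 = self.random_dm(5, 2)
        d2 = self.random_dm(5, 3)
        exact = exhaustive_mantel(d1.values.to_numpy(), d2.values.to_numpy())
        approx = pv.mantel(d1, d2, n_perm=6000, seed=4)
        assert approx["r"] == pytest.approx(exact["r"])
        assert approx["p"] == pytest.approx(exact["p"], abs=0.02)

    def test_agrees_with_skbio(self):
        skbio_dist = pytest.importorskip("skbio.stats.distance")
        d1 = self.random_dm(10, 5)
        d2 = self.random_dm(10, 6)
        r_sk, p_sk, _ = skbio_dist.mantel(
            skbio_dist.DistanceMatrix(d1.values.to_numpy()),
            skbio_dist.DistanceMatrix(d2.values.to_numpy()),
            permutations=999,
            alternative="two-sided",
        )
        res = pv.mantel(d1, d2, n_perm=999, seed=7)
        assert res["r"] == pytest.approx(float(r_sk), abs=1e-10)
        assert res["p"] == pytest.approx(float(p_sk), abs=0.06)

    def test_dimension_mismatch(self):
        with pytest.raises(ValidationError):
            pv.mantel(self.random_dm(5, 0), self.random_dm(6, 0), n_perm=9)
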