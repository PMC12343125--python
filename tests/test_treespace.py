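"""Tree distances, PCoA embedding, landscape/density/spread analytics."""

import itertools

import numpy as np
import pytest

from fbdstrata.trees import TreeSample, tree_from_newick
from fbdstrata.treespace import (TreespaceEmbedding, clustering_info_distance,
                                 density_map, distance_matrix, idw, landscape,
                                 pcoa_embed, rf_distance, spread_stats)
from tests_support import best_matching_value, random_trees


def t(newick):
    return tree_from_newick(newick)


class TestRF:
    def test_identical_zero(self):
        a = t("((A:1,B:1):1,(C:1,D:1):1);")
        assert rf_distance(a, a.copy()) == 0

    def test_four_taxon_disjoint_splits(self):
        a = t("((A:1,B:1):1,(C:1,D:1):1);")
        b = t("((A:1,C:1):1,(B:1,D:1):1);")
        assert rf_distance(a, b) == 2

    def test_max_bound_five_taxa(self, rng):
        trees = random_trees(5, 20, rng)
        for a, b in itertools.combinations(trees, 2):
            assert rf_distance(a, b) <= 2 * (5 - 3)

    def test_matches_dendropy(self, rng):
        import dendropy
        from dendropy.calculate import treecompare

        from fbdstrata.trees import write_trees

        trees = random_trees(7, 10, rng)
        tns = dendropy.TaxonNamespace()
        dts = []
        for dt in trees:
            cp = dt.copy()
            cp.tree.migrate_taxon_namespace(tns)
            cp.tree.encode_bipartitions()
            dts.append(cp.tree)
        for (i, a), (j, b) in itertools.combinations(enumerate(dts), 2):
            expected = treecompare.symmetric_difference(a, b)
            assert rf_distance(trees[i], trees[j]) == expected

    def test_leafset_mismatch(self):
        with pytest.raises(ValueError):
            rf_distance(t("(A:1,B:1);"), t("(A:1,C:1);"))


class TestClusteringInfo:
    def test_identical_zero(self, rng):
        for dt in random_trees(6, 5, rng):
            assert clustering_info_distance(dt, dt.copy()) == pytest.approx(0.0)

    def test_symmetry(self, rng):
        trees = random_trees(6, 12, rng)
        for a, b in itertools.combinations(trees, 2):
            assert clustering_info_distance(a, b) == pytest.approx(
                clustering_info_distance(b, a))

    def test_matches_exhaustive_matching(self, rng):
        """Optimal-assignment value equals brute-force permutation search."""
        from fbdstrata.splits import taxon_index, tree_splits
        from fbdstrata.treespace import (_mutual_clustering_info,
                                         _split_entropy)

        trees = random_trees(6, 8, rng)
        index = taxon_index(trees[0].taxa)
        n = len(index)
        for a, b in itertools.combinations(trees, 2):
            s1, s2 = sorted(tree_splits(a, index)), sorted(tree_splits(b, index))
            rows = [[_mutual_clustering_info(x, y, n) for y in s2] for x in s1]
            h = (sum(_split_entropy(m, n) for m in s1)
                 + sum(_split_entropy(m, n) for m in s2))
            expected = max(0.0, h - 2 * best_matching_value(rows))
            assert clustering_info_distance(a, b) == pytest.approx(expected)

    def test_metric_axioms(self, rng):
        trees = random_trees(7, 10, rng)
        D = distance_matrix(TreeSample(trees), metric="cid")
        assert np.allclose(D, D.T) and np.allclose(np.diag(D), 0)
        m = len(trees)
        for i, j, k in itertools.permutations(range(m), 3):
            assert D[i, j] <= D[i, k] + D[k, j] + 1e-9


class TestDistanceMatrix:
    def test_identical_sample_zero_matrix(self, rng):
        dt = random_trees(6, 1, rng)[0]
        D = distance_matrix(TreeSample([dt.copy() for _ in range(4)]), "cid")
        assert np.allclose(D, 0)

    def test_singleton(self, rng):
        D = distance_matrix(TreeSample(random_trees(5, 1, rng)), "rf")
        assert D.shape == (1, 1) and D[0, 0] == 0

    def test_rf_metric_properties(self, rng):
        trees = random_trees(6, 12, rng)
        D = distance_matrix(TreeSample(trees), metric="rf")
        m = len(trees)
        pairs = [(i, j) for i in range(m) for j in range(i + 1, m)]
        for i, j in pairs:
            assert D[i, j] == rf_distance(trees[i], trees[j])
        for i, j, k in itertools.permutations(range(m), 3):
            assert D[i, j] <= D[i, k] + D[k, j]


class TestPCoA:
    def test_three_collinear_points(self):
        D = np.array([[0.0, 1, 2], [1, 0, 1], [2, 1, 0]])
        emb = pcoa_embed(D)
        x = np.sort(emb.coords[:, 0])
        assert x == pytest.approx([-1.0, 0.0, 1.0])

    def test_all_zero_distances(self):
        emb = pcoa_embed(np.zeros((4, 4)))
        assert np.allclose(emb.coords, 0)

    def test_recovers_planted_euclidean_configuration(self, rng):
        pts = rng.normal(size=(15, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        emb = pcoa_embed(D)
        rec = np.linalg.norm(emb.coords[:, None] - emb.coords[None, :], axis=2)
        assert np.max(np.abs(rec - D)) < 1e-8
        # Procrustes error against the planted configuration
        from scipy.spatial import procrustes

        _, _, disparity = procrustes(pts, emb.coords[:, :2])
        assert disparity < 1e-8

    def test_eigenvalues_nonincreasing(self, rng):
        trees = random_trees(6, 10, rng)
        emb = pcoa_embed(distance_matrix(TreeSample(trees), "rf"))
        assert (np.diff(emb.eigenvalues) <= 1e-9).all()

    def test_identical_split_sets_identical_coords(self, rng):
        dt = random_trees(6, 1, rng)[0]
        trees = [dt, dt.copy()] + random_trees(6, 4, rng)
        emb = pcoa_embed(distance_matrix(TreeSample(trees), "cid"))
        assert emb.coords[0] == pytest.approx(emb.coords[1], abs=1e-8)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            pcoa_embed(np.array([[0.0, 1], [2, 0]]))


def embedding_of(points, **kw):
    return TreespaceEmbedding(coords=np.asarray(points, dtype=float),
                              eigenvalues=np.array([1.0]), **kw)


class TestLandscape:
    def test_constant_values_flat_surface(self, rng):
        emb = embedding_of(rng.normal(size=(10, 2)))
        surf = landscape(emb, values=np.full(10, 3.5))
        inside = surf.grid_z[~np.isnan(surf.grid_z)]
        assert inside == pytest.approx(np.full(inside.shape, 3.5))

    def test_exact_at_data_points(self, rng):
        pts = rng.normal(size=(8, 2))
        vals = rng.uniform(0, 10, 8)
        surf = landscape(embedding_of(pts), values=vals)
        assert surf.interpolate(pts) == pytest.approx(vals)

    def test_gradient_between_two_clusters(self):
        pts = np.array([[0.0, 0], [0.1, 0], [5.0, 0], [5.1, 0]])
        surf = landscape(embedding_of(pts), values=np.array([0.0, 0, 10, 10]))
        line = surf.interpolate(np.column_stack(
            [np.linspace(0.3, 4.9, 12), np.zeros(12)]))
        assert (np.diff(line) > 0).all()

    def test_order_invariance(self, rng):
        pts = rng.normal(size=(9, 2))
        vals = rng.uniform(size=9)
        a = landscape(embedding_of(pts), values=vals)
        perm = rng.permutation(9)
        b = landscape(embedding_of(pts[perm]), values=vals[perm])
        assert a.grid_z == pytest.approx(b.grid_z, nan_ok=True)


class TestDensity:
    def test_normalization(self, rng):
        emb = embedding_of(rng.normal(size=(200, 2)),
                           groups=["g"] * 200)
        (gx, gy, Z) = density_map(emb)["g"]
        integral = Z.sum() * (gx[1] - gx[0]) * (gy[1] - gy[0])
        assert integral == pytest.approx(1.0, rel=0.01)

    def test_unimodal_peak_near_centroid(self, rng):
        pts = rng.normal(loc=[2, -1], scale=0.3, size=(300, 2))
        (gx, gy, Z) = density_map(embedding_of(pts))["all"]
        iy, ix = np.unravel_index(np.argmax(Z), Z.shape)
        assert abs(gx[ix] - 2) < 0.3 and abs(gy[iy] + 1) < 0.3

    def test_degenerate_points_warn(self):
        emb = embedding_of(np.zeros((5, 2)))
        with pytest.warns(UserWarning, match="degenerate"):
            dens = density_map(emb)
        (gx, gy, Z) = dens["all"]
        assert Z.max() > 0


class TestSpread:
    def test_single_point_zero(self):
        stats = spread_stats(np.array([[1.0, 2.0]]), groups=["g"])
        assert stats["g"] == {"sum_of_variances": 0.0, "sum_of_ranges": 0.0,
                              "mean_centroid_distance": 0.0}

    def test_two_point_arithmetic(self):
        stats = spread_stats(np.array([[0.0, 0.0], [2.0, 0.0]]))["all"]
        assert stats["sum_of_variances"] == pytest.approx(1.0)  # population
        assert stats["sum_of_ranges"] == pytest.approx(2.0)
        assert stats["mean_centroid_distance"] == pytest.approx(1.0)

    def test_duplicated_cloud_invariance(self, rng):
        pts = rng.normal(size=(20, 3))
        a = spread_stats(pts)["all"]
        b = spread_stats(np.vstack([pts, pts]))["all"]
        for k in a:
            assert a[k] == pytest.approx(b[k])


def test_idw_exactness_at_singular_point():
    pts = np.array([[0.0, 0.0], [1.0, 0.0]])
    assert idw(pts, np.array([5.0, 7.0]), np.array([[0.0, 0.0]]))[0] == 5.0
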