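import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as hst

from treestrat import multivariate as MV
from treestrat import trees as T
from treestrat.bootstrap import StrategyDescriptor, build_clade_matrix

from conftest import random_rooted_tree


def two_regime_matrix(rng, n_per=6, jitter=3.0):
    """Synthetic S: one strategy group supports balanced-tree clades, the
    other caterpillar clades."""
    bal = T.read_newick("(((A,B),(C,D)),((E,F),(G,H)));")
    cat = T.read_newick("(((((((A,B),C),D),E),F),G),H);")
    labs = list("ABCDEFGH")
    clades = sorted(T.clade_masks(bal, labs) | T.clade_masks(cat, labs))
    col = {c: i for i, c in enumerate(clades)}
    X = np.zeros((2 * n_per, len(clades)))
    for g, tree in enumerate([bal, cat]):
        for r in range(n_per):
            for m in T.clade_masks(tree, labs):
                X[g * n_per + r, col[m]] = 900 + rng.integers(-50, 50)
    X += rng.normal(0, jitter, X.shape)
    return np.clip(X, 0, 1000)


class TestCladeSizeStats:
    def test_balanced_topology_mean(self):
        # T_bal clade multiset {2,2,2,2,4,4}: mean 8/3
        counts = {m: 1 for m in
                  T.clade_masks(T.read_newick("(((A,B),(C,D)),((E,F),(G,H)));"),
                                list("ABCDEFGH"))}
        _, mean, se = MV.clade_size_stats(counts)
        assert mean == pytest.approx(8 / 3)

    def test_caterpillar_topology_mean(self):
        # T_unbal clade multiset {2,...,7}: mean 4.5
        counts = {m: 1 for m in
                  T.clade_masks(T.read_newick("(((((((A,B),C),D),E),F),G),H);"),
                                list("ABCDEFGH"))}
        _, mean, _ = MV.clade_size_stats(counts)
        assert mean == 4.5

    def test_constant_sizes_have_zero_se(self):
        _, mean, se = MV.clade_size_stats({0b0011: 5, 0b1100: 7})
        assert mean == 2.0 and se == 0.0

    def test_counts_weight_instances(self):
        cdf, mean, _ = MV.clade_size_stats({0b0011: 3, 0b0111: 1})
        assert mean == pytest.approx((2 * 3 + 3 * 1) / 4)
        assert cdf[0] == pytest.approx(0.75)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            MV.clade_size_stats({})


class TestRobinsonFoulds:
    def test_identical_trees_zero(self):
        t = T.read_newick("((A,B),(C,D));")
        assert MV.robinson_foulds(t, t) == 0

    def test_cherry_swap_matches_set_difference(self):
        t1 = T.read_newick("((((A,B),C),D),E);")
        t2 = T.read_newick("((((A,C),B),D),E);")
        labs = list("ABCDE")
        expect = len(T.clade_masks(t1, labs) ^ T.clade_masks(t2, labs))
        assert MV.robinson_foulds(t1, t2) == expect

    def test_leaf_mismatch_rejected(self):
        with pytest.raises(ValueError):
            MV.robinson_foulds(T.read_newick("((A,B),C);"),
                               T.read_newick("((A,B),D);"))

    @given(hst.integers(0, 10_000))
    def test_metric_axioms_on_random_triples(self, seed):
        rng = np.random.default_rng(seed)
        labels = [f"t{i}" for i in range(6)]
        a, b, c = (random_rooted_tree(rng, labels) for _ in range(3))
        dab = MV.robinson_foulds(a, b)
        dba = MV.robinson_foulds(b, a)
        assert dab == dba
        assert dab <= MV.robinson_foulds(a, c) + MV.robinson_foulds(c, b)


class TestMeanRF:
    def test_identical_unanimous_sets_zero(self):
        ts = [T.read_newick("((A,B),C);")] * 3
        out = MV.mean_rf_matrix([ts, ts])
        assert out[0, 1] == 0

    def test_b2_matches_hand_enumeration(self):
        s1 = [T.read_newick("((((A,B),C),D),E);"),
              T.read_newick("((((A,C),B),D),E);")]
        s2 = [T.read_newick("((((A,B),D),C),E);"),
              T.read_newick("((((A,B),C),D),E);")]
        expect = np.mean([MV.robinson_foulds(x, y) for x in s1 for y in s2])
        out = MV.mean_rf_matrix([s1, s2])
        assert out[0, 1] == pytest.approx(expect)
        assert np.allclose(out, out.T)

    def test_subsampling_under_budget(self):
        rng = np.random.default_rng(0)
        labels = [f"t{i}" for i in range(6)]
        s1 = [random_rooted_tree(rng, labels) for _ in range(5)]
        s2 = [random_rooted_tree(rng, labels) for _ in range(5)]
        exact = MV.mean_rf_matrix([s1, s2])
        approx = MV.mean_rf_matrix([s1, s2], pair_budget=20,
                                   rng=np.random.default_rng(1))
        assert abs(exact[0, 1] - approx[0, 1]) < 4.0


class TestPCA:
    def test_rank_one_case_separates_groups(self):
        X = np.zeros((6, 4))
        X[:3, 0] = 100.0
        X[3:, 1] = 100.0
        emb = MV.pca_embed(X)
        s1 = set(np.sign(emb.coords[:3, 0]))
        s2 = set(np.sign(emb.coords[3:, 0]))
        assert s1 == {s1.pop()} if False else len(s1) == 1 and len(s2) == 1
        assert s1 != s2
        assert emb.variance_fractions[1] == pytest.approx(0.0, abs=1e-12)

    def test_duplicating_row_keeps_directions(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 5))
        e1 = MV.pca_embed(np.vstack([X, X[0]]))
        e2 = MV.pca_embed(np.vstack([X, X[0], X[0]]))
        # compare the leading component axis up to sign
        a = e1.coords[: 8, 0] - e1.coords[:8, 0].mean()
        b = e2.coords[: 8, 0] - e2.coords[:8, 0].mean()
        corr = abs(np.corrcoef(a, b)[0, 1])
        assert corr > 0.99

    def test_variance_fractions_bounded(self):
        rng = np.random.default_rng(4)
        emb = MV.pca_embed(rng.normal(size=(10, 6)))
        assert emb.variance_fractions.sum() <= 1.0 + 1e-12

    def test_constant_matrix_degenerate(self):
        emb = MV.pca_embed(np.ones((5, 3)))
        assert np.all(emb.coords == 0)


class TestMDS:
    def test_line_configuration_recovered(self):
        pts = np.array([0.0, 1.0, 3.0, 6.0])
        D = np.abs(pts[:, None] - pts[None, :])
        emb = MV.mds_embed(D)
        x = emb.coords[:, 0]
        gaps = np.diff(np.sort(x))
        assert np.allclose(sorted(gaps), [1, 2, 3], atol=1e-8)

    def test_zero_matrix_gives_zeros(self):
        emb = MV.mds_embed(np.zeros((4, 4)))
        assert np.allclose(emb.coords, 0)

    def test_rank2_euclidean_distances_reproduced(self):
        rng = np.random.default_rng(5)
        P = rng.normal(size=(7, 2))
        D = np.linalg.norm(P[:, None] - P[None, :], axis=2)
        emb = MV.mds_embed(D)
        D2 = np.linalg.norm(emb.coords[:, None] - emb.coords[None, :], axis=2)
        assert np.allclose(D, D2, atol=1e-8)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            MV.mds_embed(np.array([[0, 1.0], [2.0, 0]]))


def rot(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


class TestProcrustes:
    def test_similarity_transform_of_target_fits_exactly(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(10, 2))
        Y = 0.5 * X @ rot(np.pi / 6) + np.array([3.0, -1.0])
        fit = MV.procrustes_dissimilarity(X, Y)
        assert fit.dissimilarity == pytest.approx(0.0, abs=1e-10)

    def test_reflection_fits_exactly(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(8, 2))
        Y = X @ np.array([[1.0, 0.0], [0.0, -1.0]])
        fit = MV.procrustes_dissimilarity(X, Y)
        assert fit.dissimilarity == pytest.approx(0.0, abs=1e-10)

    def test_matches_scipy_reference(self):
        from scipy.spatial import procrustes as scipy_procrustes

        rng = np.random.default_rng(8)
        X, Y = rng.normal(size=(9, 2)), rng.normal(size=(9, 2))
        fit = MV.procrustes_dissimilarity(X, Y)
        _, _, disparity = scipy_procrustes(X, Y)
        assert 0.0 <= fit.dissimilarity <= 1.0
        assert fit.dissimilarity == pytest.approx(disparity, abs=1e-10)

    def test_matches_grid_search_oracle_on_three_points(self):
        rng = np.random.default_rng(9)
        X, Y = rng.normal(size=(3, 2)), rng.normal(size=(3, 2))
        Xc = X - X.mean(axis=0)
        Yc = Y - Y.mean(axis=0)
        denom = (Xc ** 2).sum()
        best = np.inf
        for refl in (1.0, -1.0):
            for theta in np.linspace(0, 2 * np.pi, 20001):
                Tm = rot(theta) @ np.diag([1.0, refl])
                Yr = Yc @ Tm
                b = (Xc * Yr).sum() / (Yr ** 2).sum()
                best = min(best, ((Xc - b * Yr) ** 2).sum() / denom)
        fit = MV.procrustes_dissimilarity(X, Y)
        assert fit.dissimilarity == pytest.approx(best, abs=1e-4)

    def test_zero_scatter_target_rejected(self):
        with pytest.raises(ValueError):
            MV.procrustes_dissimilarity(np.ones((4, 2)),
                                        np.arange(8.0).reshape(4, 2))


class TestProcrustesInfluence:
    def test_removing_nothing_is_zero(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(10, 6))
        assert MV.procrustes_influence(X, []) == pytest.approx(0.0, abs=1e-10)

    def test_removing_centroid_row_is_zero(self):
        # a strategy lying exactly at the centroid contributes nothing to the
        # principal directions, so its removal has no influence
        rng = np.random.default_rng(11)
        X = rng.normal(size=(9, 5))
        X = np.vstack([X, X.mean(axis=0)])
        assert MV.procrustes_influence(X, [9]) == pytest.approx(0.0, abs=1e-8)

    def test_removing_duplicated_row_is_small(self):
        # removing one copy of a duplicated strategy only reweights the
        # covariance slightly; the influence is small but not exactly zero
        rng = np.random.default_rng(11)
        X = rng.normal(size=(9, 5))
        X = np.vstack([X, X[0]])
        assert MV.procrustes_influence(X, [9]) < 0.05

    def test_dominant_group_more_influential_than_random(self):
        rng = np.random.default_rng(12)
        wins = 0
        for trial in range(20):
            X = two_regime_matrix(np.random.default_rng(100 + trial))
            dom = MV.procrustes_influence(X, list(range(6)))
            pick = np.random.default_rng(trial).choice(12, size=6,
                                                       replace=False)
            rnd = MV.procrustes_influence(X, list(pick))
            wins += dom >= rnd
        assert wins >= 15


class TestClustering:
    def test_ward_two_groups_merge_last(self):
        X = two_regime_matrix(np.random.default_rng(13))
        res = MV.ward_dendrogram(X, K=2)
        g1, g2 = set(res.labels[:6]), set(res.labels[6:])
        assert len(g1) == 1 and len(g2) == 1 and g1 != g2
        heights = res.merge_history[:, 2]
        assert (np.diff(heights) >= -1e-9).all()

    def test_ward_two_points_single_merge(self):
        res = MV.ward_dendrogram(np.array([[0.0, 0], [1.0, 1]]), K=2)
        assert res.merge_history.shape[0] == 1

    def test_kmeans_recovers_separated_groups(self):
        X = two_regime_matrix(np.random.default_rng(14))
        res = MV.kmeans_cluster(X, 2, restarts=20,
                                rng=np.random.default_rng(0))
        assert len(set(res.labels[:6])) == 1
        assert len(set(res.labels[6:])) == 1
        assert res.labels[0] != res.labels[-1]

    def test_kmeans_k_equals_n_gives_zero_wss(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(6, 3))
        res = MV.kmeans_cluster(X, 6, restarts=5, rng=rng)
        assert res.wss == pytest.approx(0.0, abs=1e-9)

    def test_kmeans_wss_non_increasing_in_k(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(12, 5)) * 10
        prev = np.inf
        for K in range(2, 10):
            res = MV.kmeans_cluster(X, K, restarts=20,
                                    rng=np.random.default_rng(K))
            assert res.wss <= prev + 1e-9
            prev = res.wss

    def test_pca_ward_kmeans_agree_on_two_regimes(self):
        X = two_regime_matrix(np.random.default_rng(17))
        pc1 = MV.pca_embed(X).coords[:, 0]
        split_pca = pc1 > np.median(pc1)
        ward = MV.ward_dendrogram(X, K=2).labels == 1
        km = MV.kmeans_cluster(X, 2, restarts=20,
                               rng=np.random.default_rng(1)).labels == 1
        for split in (ward, km):
            same = (split == split_pca).all() or (split == ~split_pca).all()
            assert same


class TestNonzeroCorrelation:
    def test_identical_rows(self):
        X = np.array([[1, 2, 0, 4], [1, 2, 0, 4.0]])
        assert MV.nonzero_correlation(X, 0, 1) == pytest.approx(1.0)

    def test_proportional_on_shared_support(self):
        X = np.array([[2, 4, 6, 0], [1, 2, 3, 9.0]])
        assert MV.nonzero_correlation(X, 0, 1) == pytest.approx(1.0)

    def test_hand_built_matches_pearson(self):
        a = np.array([3, 0, 2, 5, 1.0])
        b = np.array([1, 7, 4, 2, 6.0])
        X = np.vstack([a, b])
        mask = (a != 0) & (b != 0)
        expect = np.corrcoef(a[mask], b[mask])[0, 1]
        assert MV.nonzero_correlation(X, 0, 1) == pytest.approx(expect)

    def test_insufficient_shared_support_rejected(self):
        X = np.array([[1, 0, 0], [0, 1, 1.0]])
        with pytest.raises(ValueError):
            MV.nonzero_correlation(X, 0, 1)


class TestCladeFlow:
    def test_support_within_other_set_is_zero(self):
        X = np.array([[5, 5, 0], [1, 1, 1.0]])
        flow = MV.clade_flow(X)
        assert flow[0, 1] == 0.0

    def test_disjoint_sets_full_flow(self):
        X = np.array([[5, 0], [0, 3.0]])
        flow = MV.clade_flow(X)
        assert flow[0, 1] == 1.0 and flow[1, 0] == 1.0

    def test_hand_built_weighted_fraction(self):
        X = np.array([[6, 3, 1], [2, 0, 0.0]])
        flow = MV.clade_flow(X)
        assert flow[0, 1] == pytest.approx(4 / 10)
        assert flow[1, 0] == 0.0

    def test_unweighted_variant(self):
        X = np.array([[6, 3, 1], [2, 0, 0.0]])
        flow = MV.clade_flow(X, weighted=False)
        assert flow[0, 1] == pytest.approx(2 / 3)

    def test_diagonal_zero(self):
        rng = np.random.default_rng(19)
        X = rng.integers(0, 5, size=(4, 6)).astype(float)
        X[:, 0] = 1  # keep every row non-empty
        flow = MV.clade_flow(X)
        assert np.all(np.diagonal(flow) == 0)


class TestRepresentativeTopology:
    def _matrix(self):
        t_bal = T.read_newick("(((A,B),(C,D)),((E,F),(G,H)));")
        trees = [t_bal] * 4
        from treestrat.bootstrap import collect_clades

        rows = [
            (StrategyDescriptor("star", "nj", "o1"), collect_clades(trees)),
            (StrategyDescriptor("star", "nj", "o2"), collect_clades(trees)),
        ]
        return build_clade_matrix(rows, 4, list("ABCDEFGH"))

    def test_singleton_subset_equals_greedy_of_row(self):
        S = self._matrix()
        t1 = MV.representative_topology(S, [0])
        labs = S.labels
        assert T.clade_masks(t1, labs) == T.clade_masks(
            T.read_newick("(((A,B),(C,D)),((E,F),(G,H)));"), labs
        )

    def test_identical_rows_average_to_same_tree(self):
        S = self._matrix()
        t1 = MV.representative_topology(S, [0])
        t2 = MV.representative_topology(S, [0, 1])
        labs = S.labels
        assert T.clade_masks(t1, labs) == T.clade_masks(t2, labs)

    def test_averaged_supports_bounded_by_B(self):
        S = self._matrix()
        tree = MV.representative_topology(S, [0, 1])
        for node in tree.preorder_node_iter():
            if node.label is not None:
                assert float(node.label) <= S.B
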