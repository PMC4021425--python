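import itertools
import math

import dendropy
import numpy as np
import pytest
from hypothesis import given, strategies as hst

from treestrat import genetrees as G
from treestrat import trees as T
from treestrat.distances import SpeciesDistanceMatrix, UndefinedDistanceError
from treestrat.submodel import jc_model

from conftest import (enumerate_unrooted, make_dataset, make_locus,
                      random_additive_matrix, splits)


class TestNeighborJoining:
    def test_additive_matrix_recovered_exactly(self):
        # tree ((A:1,B:2):1,(C:1,D:1):1)
        vals = np.array([
            [0, 3, 3, 3.0],
            [3, 0, 4, 4.0],
            [3, 4, 0, 2.0],
            [3, 4, 2, 0.0],
        ])
        m = SpeciesDistanceMatrix(list("ABCD"), vals)
        tree = G.neighbor_joining(m)
        labs, sp = splits(tree)
        assert sp == {0b0011} or sp == {0b1100}
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(2.0)

    def test_three_taxa_star(self):
        m = SpeciesDistanceMatrix(list("ABC"),
                                  np.array([[0, 2, 3.], [2, 0, 4.], [3, 4, 0]]))
        tree = G.neighbor_joining(m)
        assert sorted(T.leaf_labels(tree)) == ["A", "B", "C"]

    def test_incomplete_matrix_rejected(self):
        m = SpeciesDistanceMatrix(
            list("ABC"), np.zeros((3, 3)),
            undefined=np.eye(3, k=1, dtype=bool) | np.eye(3, k=-1, dtype=bool),
        )
        with pytest.raises(UndefinedDistanceError):
            G.neighbor_joining(m)

    @given(hst.integers(0, 10_000))
    def test_random_additive_trees_recovered(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 11))
        tree, m = random_additive_matrix(rng, n)
        out = G.neighbor_joining(m)
        assert splits(tree) == splits(out)
        for e in out.preorder_edge_iter():
            if e.tail_node is not None:
                assert e.length >= 0


class TestFitch:
    def test_hand_scored_columns(self):
        aln = make_locus({"A": "AA", "B": "AA", "C": "TT", "D": "TT"})
        assert G.fitch_score(aln, T.read_newick("((A,B),(C,D));")) == 2
        assert G.fitch_score(aln, T.read_newick("((A,C),(B,D));")) == 4

    def test_invariant_column_costs_zero(self):
        aln = make_locus({"A": "G", "B": "G", "C": "G", "D": "G"})
        assert G.fitch_score(aln, T.read_newick("((A,B),(C,D));")) == 0

    def test_gaps_are_free_ambiguity(self):
        aln = make_locus({"A": "A", "B": "-", "C": "A", "D": "?"})
        assert G.fitch_score(aln, T.read_newick("((A,B),(C,D));")) == 0

    def test_label_mismatch_rejected(self):
        aln = make_locus({"A": "A", "B": "A"})
        with pytest.raises(ValueError):
            G.fitch_score(aln, T.read_newick("((A,B),(C,D));"))


class TestParsimonySearch:
    @given(hst.integers(0, 10_000))
    def test_exact_search_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 8))
        labels = [f"t{i}" for i in range(n)]
        seqs = {
            lab: "".join(rng.choice(list("ACGT"), size=12)) for lab in labels
        }
        aln = make_locus(seqs)
        best = min(
            G.fitch_score(aln, T.read_newick(nwk))
            for nwk in enumerate_unrooted(labels)
        )
        tree = G.parsimony_search(aln, rng)
        assert G.fitch_score(aln, tree) == best

    def test_high_signal_caterpillar_recovered(self):
        # strongly nested signal: each column supports one caterpillar split
        labels = list("ABCDEF")
        cols = []
        for k in range(2, 5):
            for _ in range(10):
                cols.append(["T" if i < k else "A" for i in range(6)])
        seqs = {lab: "".join(c[i] for c in cols) for i, lab in enumerate(labels)}
        aln = make_locus(seqs)
        tree = G.parsimony_search(aln, np.random.default_rng(0))
        _, sp = splits(tree)
        assert sp == {0b000011, 0b000111, 0b001111}

    def test_co_optimal_trees_chosen_uniformly(self):
        # two topologies tie; over many seeds both appear near 50/50
        aln = make_locus({"A": "AA", "B": "AT", "C": "TA", "D": "TT"})
        hits = 0
        n = 200
        for seed in range(n):
            tree = G.parsimony_search(aln, np.random.default_rng(seed))
            _, sp = splits(tree)
            hits += sp == {0b0011}
        assert 0.35 < hits / n < 0.65

    def test_hill_climb_beyond_exact_limit(self):
        rng = np.random.default_rng(1)
        labels = [f"t{i}" for i in range(6)]
        seqs = {lab: "".join(rng.choice(list("ACGT"), size=30))
                for lab in labels}
        aln = make_locus(seqs)
        exact = G.parsimony_search(aln, np.random.default_rng(2))
        heur = G.parsimony_search(aln, np.random.default_rng(2), exact_limit=4)
        assert G.fitch_score(aln, heur) >= G.fitch_score(aln, exact)


class TestGTRLikelihood:
    def test_jc_closed_form_single_column(self):
        t = 0.3
        model = jc_model()
        same = make_locus({"A": "A", "B": "A"})
        diff = make_locus({"A": "A", "B": "G"})
        tree = T.read_newick(f"(A:{t/2},B:{t/2});")
        p_same = 0.25 + 0.75 * math.exp(-4 * t / 3)
        p_diff = 0.25 - 0.25 * math.exp(-4 * t / 3)
        assert G.gtr_log_likelihood(same, tree, model) == pytest.approx(
            math.log(0.25 * p_same), abs=1e-10
        )
        assert G.gtr_log_likelihood(diff, tree, model) == pytest.approx(
            math.log(0.25 * p_diff), abs=1e-10
        )

    def test_invariant_under_rerooting(self):
        rng = np.random.default_rng(0)
        seqs = {lab: "".join(rng.choice(list("ACGT"), size=40))
                for lab in "ABCD"}
        aln = make_locus(seqs)
        model = jc_model()
        t1 = T.read_newick("((A:0.1,B:0.2):0.05,C:0.3,D:0.4);")
        t2 = T.read_newick("((C:0.3,D:0.4):0.05,A:0.1,B:0.2);")
        assert G.gtr_log_likelihood(aln, t1, model) == pytest.approx(
            G.gtr_log_likelihood(aln, t2, model), abs=1e-9
        )

    def test_zero_length_star_identical_sequences(self):
        aln = make_locus({"A": "ACGT", "B": "ACGT", "C": "ACGT"})
        tree = T.read_newick("(A:0,B:0,C:0);")
        ll = G.gtr_log_likelihood(aln, tree, jc_model())
        assert ll == pytest.approx(4 * math.log(0.25), abs=1e-10)


class TestMLSearch:
    @staticmethod
    def _signal_alignment(rng, nwk, length=800):
        from treestrat import simulate as sim

        sp = T.read_newick(nwk)
        model = sim.MSCModel(sp, {l.taxon.label: 1 for l in sp.leaf_node_iter()},
                             locus_length=length,
                             substitution_model=jc_model(), scale=0.01)
        gt = sim.simulate_msc_gene_tree(model, rng)
        aln = sim.simulate_alignment(gt, model, rng)
        recs = [type(r)(r.individual_id.rsplit("_", 1)[0],
                        r.species_id, r.locus_id, r.residues)
                for r in aln.records]
        return make_locus({r.individual_id: r.residues for r in recs}), gt

    def test_four_taxon_matches_exhaustive_optimization(self):
        from scipy.optimize import minimize

        rng = np.random.default_rng(8)
        aln, _ = self._signal_alignment(
            rng, "((A:1,B:1):3,(C:1,D:1):3);", length=400
        )
        model = G.gtr_model(np.ones(6), G.empirical_frequencies(aln))
        best_oracle = -np.inf
        for nwk in ["((A,B),(C,D));", "((A,C),(B,D));", "((A,D),(B,C));"]:
            topo = T.read_newick(nwk)
            edges = [e for e in topo.preorder_edge_iter()
                     if e.tail_node is not None]

            def neg(logt):
                for e, v in zip(edges, np.exp(logt)):
                    e.length = float(v)
                return -G.gtr_log_likelihood(aln, topo, model)

            res = minimize(neg, np.full(len(edges), -2.0), method="Nelder-Mead",
                           options={"maxiter": 2000, "fatol": 1e-10})
            best_oracle = max(best_oracle, -res.fun)
        tree = G.ml_search(aln, np.random.default_rng(9))
        # under the same fixed model, the searched topology re-optimized must
        # reach the exhaustive optimum
        labels = sorted(T.leaf_labels(tree))
        part, weights = G._partial_patterns(aln, labels)
        idx = {lab: i for i, lab in enumerate(labels)}
        ll = G._optimize_branches(tree, part, weights, idx, model)
        assert ll >= best_oracle - 1e-4
        _, sp = splits(tree)
        assert sp == {0b0011} or sp == {0b1100}

    def test_improves_on_nj_start(self):
        rng = np.random.default_rng(10)
        aln, _ = self._signal_alignment(
            rng, "(((A:1,B:1):1,(C:1,D:1):1):2,E:4);", length=600
        )
        start = G.neighbor_joining(G.alignment_distance_matrix(aln))
        for e in start.preorder_edge_iter():
            if e.tail_node is not None and (e.length is None or e.length <= 0):
                e.length = 1e-6
        model = G.gtr_model(np.ones(6), G.empirical_frequencies(aln))
        ll_start = G.gtr_log_likelihood(aln, start, model)
        tree = G.ml_search(aln, rng)
        ll_end = G.gtr_log_likelihood(aln, tree, model)
        assert ll_end >= ll_start - 1e-9

    def test_identical_sequences_return_star_with_zero_lengths(self):
        aln = make_locus({lab: "ACGTACGT" for lab in "ABCD"})
        tree = G.ml_search(aln, np.random.default_rng(0))
        assert sorted(T.leaf_labels(tree)) == list("ABCD")
        for e in tree.preorder_edge_iter():
            if e.tail_node is not None:
                assert e.length == 0.0


class TestMTree:
    def _dataset(self):
        seqs = {
            "a_1": "AAAAAAAAAA", "a_2": "AAAAAAAAAC",
            "b_1": "AAAAACCCCC", "b_2": "AAAAACCCCA",
            "c_1": "CCCCCCCCCC", "c_2": "CCCCCCCCCA",
            "o_1": "GGGGGGGGGG",
        }
        smap = {k: k.split("_")[0] for k in seqs}
        return make_dataset([make_locus(seqs, species=smap)], smap,
                            ["a", "b", "c"], ["o"])

    def test_single_individual_reduces_to_plain_nj(self):
        seqs = {"a": "AAAA", "b": "AACC", "c": "CCCC", "o": "GGGG"}
        smap = {k: k for k in seqs}
        ds = make_dataset([make_locus(seqs, species=smap)], smap,
                          ["a", "b", "c"], ["o"])
        from treestrat.distances import single_individual_matrix

        t1 = G.infer_m_tree(ds.loci, ds, "pooled")
        t2 = G.neighbor_joining(single_individual_matrix(ds.loci[0]))
        assert splits(t1) == splits(t2)

    def test_pooled_on_repeated_locus_equals_per_locus(self):
        ds = self._dataset()
        rep = [ds.loci[0]] * 5
        t1 = G.infer_m_tree(rep, ds, "pooled")
        t2 = G.infer_m_tree([ds.loci[0]], ds, "per_locus")
        assert splits(t1) == splits(t2)

    def test_leaf_set_is_species_set(self):
        ds = self._dataset()
        tree = G.infer_m_tree(ds.loci, ds, "pooled")
        assert sorted(T.leaf_labels(tree)) == sorted(ds.species)


class TestRooting:
    def test_root_and_prune(self):
        un = T.read_newick("((A,B),(C,O));")
        un.is_rooted = False
        rooted = T.root_with_outgroup(un, "O", prune_outgroup=True)
        assert rooted.is_rooted
        assert T.clade_masks(rooted, ["A", "B", "C"]) == frozenset({0b011})

    def test_root_then_unroot_preserves_splits(self):
        un = T.read_newick("((A:1,B:1):1,(C:1,(D:1,O:1):1):1);")
        un.is_rooted = False
        rooted = T.root_with_outgroup(un, "O")
        assert splits(un) == splits(rooted)

    def test_missing_outgroup_rejected(self):
        t = T.read_newick("((A,B),C);")
        with pytest.raises(ValueError):
            T.root_with_outgroup(t, "Z")
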