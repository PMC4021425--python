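"""Gene-tree inference: neighbor-joining, Fitch parsimony, GTR maximum
likelihood, and neighbor-joining on multi-individual species distances (M).

Alignment rows may be labeled by individuals or species; the inferred tree
carries whatever labels the rows carry.  Gaps and missing data are treated as
fully ambiguous states in parsimony and likelihood; the p-distance paths
exclude them from overlap counts instead.
"""

from __future__ import annotations

import itertools
import logging
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
from scipy.optimize import minimize, minimize_scalar
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import nj as _skbio_nj

from . import trees as _trees
from .distances import (SpeciesDistanceMatrix, UndefinedDistanceError,
                        p_distance, species_distance_per_locus,
                        species_distance_pooled)
from .io import LocusAlignment, MultilocusDataset
from .submodel import NUCLEOTIDES, SubstitutionModel, gtr_model
from .trees import read_newick, root_with_outgroup  # re-exported

log = logging.getLogger("treestrat")

__all__ = [
    "neighbor_joining",
    "alignment_distance_matrix",
    "fitch_score",
    "parsimony_search",
    "gtr_log_likelihood",
    "ml_search",
    "infer_m_tree",
    "infer_gene_tree",
    "root_with_outgroup",
]

# ---------------------------------------------------------------------------
# neighbor-joining


def neighbor_joining(matrix: SpeciesDistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor-joining; negative branch lengths clamped to zero.

    Three taxa yield the unique (star) resolution.  The matrix must be
    complete.
    """
    if not matrix.complete:
        raise UndefinedDistanceError("distance matrix has undefined entries")
    if len(matrix.labels) < 3:
        raise ValueError("neighbor-joining needs >= 3 taxa")
    dm = _SkbioDM(matrix.values, ids=list(matrix.labels))
    newick = str(_skbio_nj(dm, neg_as_zero=True))
    tree = read_newick(newick)
    tree.is_rooted = False
    return tree


def alignment_distance_matrix(aln: LocusAlignment) -> SpeciesDistanceMatrix:
    """Pairwise p-distance matrix between alignment rows (one per label)."""
    labels = [r.individual_id for r in aln.records]
    k = len(labels)
    vals = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            vals[i, j] = vals[j, i] = p_distance(aln.records[i], aln.records[j])
    return SpeciesDistanceMatrix(labels, vals, "single_individual")


# ---------------------------------------------------------------------------
# Fitch parsimony

_STATE_BITS = {"A": 1, "C": 2, "G": 4, "T": 8, "-": 15, "?": 15}


def _encode_patterns(aln: LocusAlignment, order: Sequence[str]) -> Tuple[np.ndarray, np.ndarray]:
    """Bitmask state matrix (taxa x patterns) with pattern weights."""
    by_id = {r.individual_id: r for r in aln.records}
    rows = []
    for lab in order:
        rec = by_id.get(lab)
        if rec is None:
            raise ValueError(f"leaf {lab!r} absent from alignment")
        rows.append([_STATE_BITS[c] for c in rec.residues])
    M = np.asarray(rows, dtype=np.uint8)
    cols, weights = np.unique(M, axis=1, return_counts=True)
    return cols, weights.astype(np.int64)


def _fitch_tuple(node, states: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Fitch downpass on a nested-tuple topology; returns (state sets, costs)."""
    if isinstance(node, int):
        return states[node], np.zeros(states.shape[1], dtype=np.int64)
    sets = None
    cost = np.zeros(states.shape[1], dtype=np.int64)
    for child in node:
        s, c = _fitch_tuple(child, states)
        cost += c
        if sets is None:
            sets = s
        else:
            inter = sets & s
            union = sets | s
            empty = inter == 0
            cost += empty.astype(np.int64)
            sets = np.where(empty, union, inter)
    return sets, cost


def fitch_score(aln: LocusAlignment, topology: dendropy.Tree) -> int:
    """Fitch parsimony length of a topology on an alignment (gaps ambiguous)."""
    order = _trees.leaf_labels(topology)
    states, weights = _encode_patterns(aln, order)
    tup = _tree_to_tuple(topology, {lab: i for i, lab in enumerate(order)})
    _, cost = _fitch_tuple(tup, states)
    return int((cost * weights).sum())


def _tree_to_tuple(tree: dendropy.Tree, index: Dict[str, int]):
    def conv(node):
        if node.is_leaf():
            return index[node.taxon.label]
        return tuple(conv(c) for c in node.child_nodes())
    return conv(tree.seed_node)


def _tuple_to_tree(tup, labels: Sequence[str], rooted: bool = False) -> dendropy.Tree:
    def render(node) -> str:
        if isinstance(node, int):
            return labels[node]
        return "(" + ",".join(render(c) for c in node) + ")"
    tree = read_newick(render(tup) + ";")
    tree.is_rooted = rooted
    return tree


def _insert_taxon(tree, leaf: int):
    """Yield every topology obtained by attaching ``leaf`` on an edge of the
    unrooted tree.  Representation: nested tuple rooted at an arbitrary
    trifurcating base."""
    # attach at the base (new cherry with existing subtree) handled by
    # attaching inside each child position recursively
    def attach(node):
        # attach on the edge above `node`
        yield (node, leaf)
        if not isinstance(node, int):
            for i, child in enumerate(node):
                for sub in attach(child):
                    yield tuple(sub if j == i else c for j, c in enumerate(node))
    if isinstance(tree, int):
        yield (tree, leaf)
        return
    for i, child in enumerate(tree):
        for sub in attach(child):
            yield tuple(sub if j == i else c for j, c in enumerate(tree))


def parsimony_search(
    aln: LocusAlignment,
    rng: np.random.Generator,
    exact_limit: int = 8,
    max_coptimal: int = 1000,
) -> dendropy.Tree:
    """Maximum-parsimony topology.

    Up to ``exact_limit`` taxa: branch-and-bound over unrooted topologies by
    stepwise addition; among co-optimal trees one is drawn uniformly from the
    seeded stream.  Beyond the limit: NNI hill-climb from the NJ tree.
    Branch lengths are Fitch changes per branch per site (used downstream as
    rough coalescence-time surrogates).
    """
    labels = [r.individual_id for r in aln.records]
    n = len(labels)
    if n < 4:
        raise ValueError("parsimony search needs >= 4 taxa")
    index = {lab: i for i, lab in enumerate(labels)}
    states, weights = _encode_patterns(aln, labels)

    def score(tup) -> int:
        _, cost = _fitch_tuple(tup, states)
        return int((cost * weights).sum())

    if n <= exact_limit:
        best_score = np.inf
        best: List[tuple] = []

        def recurse(tree, remaining: List[int]):
            nonlocal best_score, best
            s = score(tree)
            if s > best_score:
                return
            if not remaining:
                if s < best_score:
                    best_score = s
                    best = [tree]
                elif len(best) < max_coptimal:
                    best.append(tree)
                return
            leaf, rest = remaining[0], remaining[1:]
            for cand in _insert_taxon(tree, leaf):
                recurse(cand, rest)

        recurse((0, 1, 2), list(range(3, n)))
        chosen = best[rng.integers(len(best))] if len(best) > 1 else best[0]
        tree = _tuple_to_tree(chosen, labels, rooted=False)
    else:
        tree = neighbor_joining(alignment_distance_matrix(aln))
        tree = _nni_hill_climb_mp(tree, aln, rng)
    _assign_parsimony_lengths(tree, aln)
    return tree


def _nni_hill_climb_mp(tree, aln, rng) -> dendropy.Tree:
    labels = _trees.leaf_labels(tree)
    index = {lab: i for i, lab in enumerate(labels)}
    states, weights = _encode_patterns(aln, labels)

    def sc(t) -> int:
        tup = _tree_to_tuple(t, index)
        _, cost = _fitch_tuple(tup, states)
        return int((cost * weights).sum())

    current, cur_score = tree, sc(tree)
    improved = True
    while improved:
        improved = False
        for cand in _nni_neighbors(current):
            s = sc(cand)
            if s < cur_score:
                current, cur_score = cand, s
                improved = True
                break
    return current


def _nni_neighbors(tree: dendropy.Tree) -> Iterable[dendropy.Tree]:
    """All NNI rearrangements of an (un)rooted binary tree, as fresh clones."""
    edges = [
        e for e in tree.preorder_edge_iter()
        if e.tail_node is not None and not e.head_node.is_leaf()
    ]
    for ei in range(len(edges)):
        for which in (0, 1):
            clone = tree.clone(depth=1)
            cedges = [
                e for e in clone.preorder_edge_iter()
                if e.tail_node is not None and not e.head_node.is_leaf()
            ]
            e = cedges[ei]
            v, u = e.head_node, e.tail_node
            vkids = v.child_nodes()
            ukids = [c for c in u.child_nodes() if c is not v]
            if not ukids or len(vkids) != 2:
                continue
            a = vkids[which]
            c = ukids[0]
            v.remove_child(a)
            u.remove_child(c)
            v.add_child(c)
            u.add_child(a)
            yield clone


def _assign_parsimony_lengths(tree: dendropy.Tree, aln: LocusAlignment) -> None:
    """Branch lengths = Fitch state changes per branch / alignment length.

    Uses the downpass state sets with a greedy uppass resolution; among the
    minimal-change resolutions an arbitrary (deterministic) one is taken.
    """
    order = _trees.leaf_labels(tree)
    states, weights = _encode_patterns(aln, order)
    idx = {lab: i for i, lab in enumerate(order)}
    down: Dict[dendropy.Node, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            down[node] = states[idx[node.taxon.label]]
        else:
            sets = None
            for ch in node.child_nodes():
                s = down[ch]
                if sets is None:
                    sets = s
                else:
                    inter = sets & s
                    sets = np.where(inter == 0, sets | s, inter)
            down[node] = sets
    chosen: Dict[dendropy.Node, np.ndarray] = {}
    ncols = aln.length
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            s = down[node]
            chosen[node] = s & (~s + 1)  # lowest set bit
            continue
        p = chosen[node.parent_node]
        s = down[node]
        keep = s & p
        pick = np.where(keep != 0, keep, s & (~s + 1))
        pick = pick & (~pick + 1)
        chosen[node] = pick
        changes = ((pick & p) == 0).astype(np.int64)
        node.edge.length = float((changes * weights).sum()) / ncols


# ---------------------------------------------------------------------------
# GTR maximum likelihood

_STATE_INDEX = {c: i for i, c in enumerate(NUCLEOTIDES)}


def _partial_patterns(aln: LocusAlignment, order: Sequence[str]) -> Tuple[np.ndarray, np.ndarray]:
    """Leaf partial likelihoods (taxa x patterns x 4) with pattern weights."""
    by_id = {r.individual_id: r for r in aln.records}
    rows = []
    for lab in order:
        rec = by_id.get(lab)
        if rec is None:
            raise ValueError(f"leaf {lab!r} absent from alignment")
        rows.append([_STATE_BITS[c] for c in rec.residues])
    M = np.asarray(rows, dtype=np.uint8)
    cols, weights = np.unique(M, axis=1, return_counts=True)
    part = np.zeros((len(order), cols.shape[1], 4))
    for s in range(4):
        part[:, :, s] = (cols >> s & 1).astype(float)
    return part, weights.astype(float)


def empirical_frequencies(aln: LocusAlignment) -> np.ndarray:
    counts = np.ones(4)  # +1 pseudocount keeps frequencies positive
    for rec in aln.records:
        for c in rec.residues:
            if c in _STATE_INDEX:
                counts[_STATE_INDEX[c]] += 1
    return counts / counts.sum()


def gtr_log_likelihood(
    aln: LocusAlignment, tree: dendropy.Tree, model: SubstitutionModel
) -> float:
    """Felsenstein pruning log-likelihood; gaps/missing contribute all-ones
    partials.  The likelihood is invariant to the root position for this
    reversible model."""
    order = _trees.leaf_labels(tree)
    part, weights = _partial_patterns(aln, order)
    idx = {lab: i for i, lab in enumerate(order)}
    return _loglik(tree, part, weights, idx, model)


def _loglik(tree, part, weights, idx, model) -> float:
    partials: Dict[dendropy.Node, np.ndarray] = {}
    scale_log = 0.0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            partials[node] = part[idx[node.taxon.label]]
            continue
        prod = None
        for ch in node.child_nodes():
            t = ch.edge.length or 0.0
            P = model.transition_matrix(t)
            msg = partials[ch] @ P.T
            prod = msg if prod is None else prod * msg
        mx = prod.max(axis=1, keepdims=True)
        mx = np.where(mx > 0, mx, 1.0)
        scale_log += float((np.log(mx[:, 0]) * weights).sum())
        partials[node] = prod / mx
    root = partials[tree.seed_node]
    site = root @ model.freqs
    site = np.where(site > 0, site, 1e-300)
    return float((np.log(site) * weights).sum()) + scale_log


def _optimize_branches(tree, part, weights, idx, model, rel_tol=1e-6) -> float:
    best = _loglik(tree, part, weights, idx, model)
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue

        def neg(t, e=edge):
            e.length = float(t)
            return -_loglik(tree, part, weights, idx, model)

        res = minimize_scalar(neg, bounds=(1e-9, 10.0), method="bounded",
                              options={"xatol": rel_tol})
        edge.length = float(res.x)
        best = -res.fun
    return best


def _optimize_rates(tree, part, weights, idx, model) -> Tuple[SubstitutionModel, float]:
    freqs = model.freqs

    def neg(logx):
        x = np.exp(np.concatenate([logx, [0.0]]))
        m = gtr_model(x, freqs)
        return -_loglik(tree, part, weights, idx, m)

    x0 = np.log(model.exchangeabilities[:5] / model.exchangeabilities[5])
    res = minimize(neg, x0, method="L-BFGS-B")
    ex = np.exp(np.concatenate([res.x, [0.0]]))
    return gtr_model(ex, freqs), -res.fun


def ml_search(
    aln: LocusAlignment,
    rng: np.random.Generator,
    max_rounds: int = 5,
    nni_tol: float = 1e-8,
) -> dendropy.Tree:
    """GTR maximum-likelihood topology search.

    Starts from the neighbor-joining tree on p-distances, alternates branch
    length optimization, exchangeability optimization (base frequencies fixed
    at empirical counts) and NNI moves accepted on log-likelihood improvement.
    Degenerate all-identical alignments return the NJ star resolution with a
    warning.
    """
    labels = [r.individual_id for r in aln.records]
    if len(labels) < 4:
        raise ValueError("ml search needs >= 4 taxa")
    dm = alignment_distance_matrix(aln)
    if not dm.values.any():
        log.warning("all sequences identical; returning NJ resolution")
        tree = neighbor_joining(dm)
        for e in tree.preorder_edge_iter():
            if e.tail_node is not None:
                e.length = 0.0
        return tree
    tree = neighbor_joining(dm)
    for e in tree.preorder_edge_iter():
        if e.tail_node is not None and (e.length is None or e.length <= 0):
            e.length = 1e-6
    part, weights = _partial_patterns(aln, labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    model = gtr_model(np.ones(6), empirical_frequencies(aln))

    best = _optimize_branches(tree, part, weights, idx, model)
    for _ in range(max_rounds):
        model, best = _optimize_rates(tree, part, weights, idx, model)
        best = _optimize_branches(tree, part, weights, idx, model)
        # NNI screen: candidates are scored after re-optimizing only their
        # swapped edge; the winner then gets a full branch sweep
        scored = []
        for cand in _nni_neighbors(tree):
            s = _optimize_one_branch(cand, part, weights, idx, model)
            scored.append((s, cand))
        improved = False
        if scored:
            smax = max(s for s, _ in scored)
            if smax > best + nni_tol:
                ties = [c for s, c in scored if s >= smax - 1e-9]
                cand = ties[int(rng.integers(len(ties)))] if len(ties) > 1 else ties[0]
                s_full = _optimize_branches(cand, part, weights, idx, model)
                if s_full > best + nni_tol:
                    tree, best = cand, s_full
                    improved = True
        if not improved:
            break
    return tree


def _optimize_one_branch(tree, part, weights, idx, model) -> float:
    """Optimize the length of the NNI focal edge only (marked by the clone)."""
    edges = [e for e in tree.preorder_edge_iter()
             if e.tail_node is not None and not e.head_node.is_leaf()]
    best = -np.inf
    for edge in edges:
        def neg(t, e=edge):
            e.length = float(t)
            return -_loglik(tree, part, weights, idx, model)
        res = minimize_scalar(neg, bounds=(1e-9, 10.0), method="bounded",
                              options={"xatol": 1e-4, "maxiter": 12})
        edge.length = float(res.x)
        best = -res.fun
    return best


# ---------------------------------------------------------------------------
# the multi-individual method (M) and dispatch


def infer_m_tree(
    loci: Sequence[LocusAlignment],
    dataset: MultilocusDataset,
    mode: str = "pooled",
    tables: Optional[dict] = None,
) -> dendropy.Tree:
    """Neighbor-joining on the species-level multi-individual distances.

    ``pooled`` uses the weighted average over the full locus multiset (the
    concatenation-type strategies); ``per_locus`` expects a single locus (the
    consensus-type strategies).  Leaves are species labels.
    """
    if mode == "pooled":
        matrix = species_distance_pooled(loci, dataset, tables=tables)
    elif mode == "per_locus":
        if len(loci) != 1:
            raise ValueError("per_locus mode expects exactly one locus")
        matrix = species_distance_per_locus(loci[0], dataset)
        if not matrix.complete:
            raise UndefinedDistanceError(
                f"undefined species distance at locus {loci[0].locus_id}"
            )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return neighbor_joining(matrix)


def infer_gene_tree(
    aln: LocusAlignment, method: str, rng: np.random.Generator
) -> dendropy.Tree:
    """Dispatch ML / MP / NJ on a one-row-per-label alignment."""
    if method == "nj":
        return neighbor_joining(alignment_distance_matrix(aln))
    if method == "mp":
        return parsimony_search(aln, rng)
    if method == "ml":
        return ml_search(aln, rng)
    raise ValueError(f"unknown gene-tree method {method!r}")
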