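"""The six species-tree estimators and their supporting algorithms.

Concatenation and SMRT (SuperMatrix Rooted Triples) are concatenation-based:
they work on a single super-locus built from the per-locus selections.  STEAC
(mean coalescence times), STAR (mean coalescence ranks), RTC (rooted-triple
consensus by triplet puzzling) and MDC (minimize deep coalescences) are
consensus methods operating on per-locus gene trees.  All estimators return a
rooted ingroup species tree (polytomies allowed for consensus outputs).

Rooted topologies are handled internally as clade bitmask sets over an ordered
label list (see :mod:`treestrat.trees`).
"""

from __future__ import annotations

import functools
import itertools
import logging
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import dendropy
import networkx as nx
import numpy as np

from . import genetrees
from .distances import SpeciesDistanceMatrix
from .io import LocusAlignment, MultilocusDataset, SequenceRecord
from .trees import (clade_masks, compatible, leaf_labels, root_with_outgroup,
                    tree_from_clades)

log = logging.getLogger("treestrat")

__all__ = [
    "RootedTriple",
    "concatenate_loci",
    "concatenation_estimate",
    "smrt_estimate",
    "mincut_supertree",
    "steac_estimate",
    "star_estimate",
    "extract_rooted_triples",
    "rtc_estimate",
    "count_extra_lineages",
    "mdc_estimate",
    "greedy_consensus",
    "enumerate_rooted_topologies",
]


@dataclass(frozen=True)
class RootedTriple:
    """ab|c: the cherry pair {a, b} is closer than the outlier c."""

    pair: FrozenSet[str]
    outlier: str
    weight: float = 1.0

    def __post_init__(self) -> None:
        if len(self.pair) != 2 or self.outlier in self.pair:
            raise ValueError("triple needs three distinct taxa")


# ---------------------------------------------------------------------------
# concatenation and SMRT


def concatenate_loci(
    loci: Sequence[LocusAlignment],
    selection: Mapping[str, Mapping[str, str]],
    species: Optional[Sequence[str]] = None,
) -> LocusAlignment:
    """Column-wise concatenation, one selected individual per species per
    locus; output rows are labeled by species.  A locus appearing twice in
    ``loci`` contributes its columns twice."""
    if not loci:
        raise ValueError("no loci to concatenate")
    if species is None:
        species = sorted(selection[loci[0].locus_id])
    parts: Dict[str, List[str]] = {sp: [] for sp in species}
    for loc in loci:
        if loc.locus_id not in selection:
            raise ValueError(f"no selection for locus {loc.locus_id!r}")
        chosen = selection[loc.locus_id]
        for sp in species:
            rec = loc.record_for(chosen[sp])
            if rec is None:
                raise ValueError(
                    f"selected individual {chosen[sp]!r} missing at {loc.locus_id}"
                )
            parts[sp].append(rec.residues)
    records = [
        SequenceRecord(sp, sp, "concatenated", "".join(parts[sp])) for sp in species
    ]
    return LocusAlignment("concatenated", records)


def _root_and_prune(tree: dendropy.Tree, outgroup: str) -> dendropy.Tree:
    return root_with_outgroup(tree, outgroup, prune_outgroup=True)


def concatenation_estimate(
    super_locus: Optional[LocusAlignment],
    gene_tree_method: str,
    outgroup: str,
    rng: np.random.Generator,
    pooled_matrix: Optional[SpeciesDistanceMatrix] = None,
) -> dendropy.Tree:
    """Concatenation: the super-gene tree, rooted with the outgroup and
    pruned to the ingroup, is the species-tree estimate.

    For the M method pass the pooled species matrix instead of an alignment.
    """
    if gene_tree_method == "m":
        if pooled_matrix is None:
            raise ValueError("M concatenation needs the pooled species matrix")
        tree = genetrees.neighbor_joining(pooled_matrix)
    else:
        tree = genetrees.infer_gene_tree(super_locus, gene_tree_method, rng)
    return _root_and_prune(tree, outgroup)


def _triple_from_tree(tree: dendropy.Tree, outgroup: str) -> Optional[RootedTriple]:
    rooted = _root_and_prune(tree, outgroup)
    labs = sorted(leaf_labels(rooted))
    masks = clade_masks(rooted, labs)
    cherries = [m for m in masks if bin(m).count("1") == 2]
    if len(cherries) != 1:
        return None
    pair = {labs[i] for i in range(3) if cherries[0] >> i & 1}
    (outlier,) = set(labs) - pair
    return RootedTriple(frozenset(pair), outlier)


def _infer_triple(
    aln4: LocusAlignment, gene_tree_method: str, outgroup: str,
    rng: np.random.Generator,
) -> Optional[RootedTriple]:
    """Rooted triple from a 3-ingroup+outgroup alignment; None when tied."""
    if gene_tree_method == "mp":
        # exhaustive over the three unrooted 4-taxon topologies; a tie means
        # the triple is unresolved and is dropped
        labs = [r.individual_id for r in aln4.records]
        best, best_score = [], None
        for (a, b), (c, d) in _quartet_splits(labs):
            nwk = f"(({a},{b}),({c},{d}));"
            t = genetrees.read_newick(nwk)
            s = genetrees.fitch_score(aln4, t)
            if best_score is None or s < best_score:
                best, best_score = [t], s
            elif s == best_score:
                best.append(t)
        if len(best) != 1:
            return None
        return _triple_from_tree(best[0], outgroup)
    tree = genetrees.infer_gene_tree(aln4, gene_tree_method, rng)
    return _triple_from_tree(tree, outgroup)


def _quartet_splits(labs: Sequence[str]):
    a, b, c, d = labs
    yield (a, b), (c, d)
    yield (a, c), (b, d)
    yield (a, d), (b, c)


def smrt_estimate(
    super_locus: Optional[LocusAlignment],
    gene_tree_method: str,
    outgroup: str,
    ingroup: Sequence[str],
    rng: np.random.Generator,
    pooled_matrix: Optional[SpeciesDistanceMatrix] = None,
) -> dendropy.Tree:
    """SuperMatrix Rooted Triples: infer all C(m,3) rooted triples from
    restricted concatenated alignments (or pooled-matrix restrictions for M)
    and assemble them with the modified mincut supertree."""
    triples: List[RootedTriple] = []
    dropped = 0
    for combo in itertools.combinations(sorted(ingroup), 3):
        if gene_tree_method == "m":
            labs = list(combo) + [outgroup]
            idx = [pooled_matrix.labels.index(l) for l in labs]
            sub = SpeciesDistanceMatrix(
                labs, pooled_matrix.values[np.ix_(idx, idx)], "pooled"
            )
            tree = genetrees.neighbor_joining(sub)
            trip = _triple_from_tree(tree, outgroup)
        else:
            aln4 = super_locus.restrict(list(combo) + [outgroup])
            trip = _infer_triple(aln4, gene_tree_method, outgroup, rng)
        if trip is None:
            dropped += 1
        else:
            triples.append(trip)
    if dropped:
        log.info("smrt: %d unresolved triples dropped", dropped)
    return mincut_supertree(triples, sorted(ingroup))


# ---------------------------------------------------------------------------
# modified mincut supertree (Aho BUILD with mincut tie-breaking)


def mincut_supertree(
    triples: Iterable[RootedTriple], labels: Sequence[str]
) -> dendropy.Tree:
    """Aho BUILD on the rooted-triple graph; when the graph is connected, all
    edges lying in some minimum-weight cut are removed (edges supported by
    every relevant input triple are protected from cutting) and the recursion
    continues on the resulting components.  Always returns a rooted tree,
    possibly polytomous."""
    triples = list(triples)
    labels = list(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    clades: List[int] = []

    def recurse(taxa: FrozenSet[str]) -> None:
        if len(taxa) > 1:
            mask = 0
            for t in taxa:
                mask |= 1 << index[t]
            clades.append(mask)
        if len(taxa) <= 2:
            if len(taxa) == 2:
                pass
            return
        relevant = [
            t for t in triples
            if t.pair <= taxa and t.outlier in taxa and t.weight > 0
        ]
        G = nx.Graph()
        G.add_nodes_from(taxa)
        total = sum(t.weight for t in relevant)
        for t in relevant:
            a, b = sorted(t.pair)
            if G.has_edge(a, b):
                G[a][b]["weight"] += t.weight
            else:
                G.add_edge(a, b, weight=t.weight)
        comps = list(nx.connected_components(G))
        if len(comps) == 1:
            comps = _mincut_components(G, total)
        if len(comps) == 1:
            return  # cannot split: polytomy over these taxa
        for comp in comps:
            recurse(frozenset(comp))

    recurse(frozenset(labels))
    full = (1 << len(labels)) - 1
    masks = {m for m in clades if m != full and bin(m).count("1") >= 2}
    return tree_from_clades(masks, labels)


def _mincut_components(G: nx.Graph, total_weight: float) -> List[set]:
    """Components after removing every edge lying in some minimum cut,
    honoring the protection of edges supported by all inputs."""
    work = nx.Graph()
    merged: Dict[str, set] = {n: {n} for n in G.nodes}
    # contract protected edges (weight equal to the total input support)
    parent = {n: n for n in G.nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b, data in G.edges(data=True):
        if data["weight"] >= total_weight and total_weight > 0:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
    groups: Dict[str, set] = {}
    for n in G.nodes:
        groups.setdefault(find(n), set()).add(n)
    if len(groups) == 1:
        return [set(G.nodes)]  # cannot split: polytomy over all taxa
    C = nx.Graph()
    C.add_nodes_from(groups)
    for a, b, data in G.edges(data=True):
        ra, rb = find(a), find(b)
        if ra == rb:
            continue
        if C.has_edge(ra, rb):
            C[ra][rb]["weight"] += data["weight"]
        else:
            C.add_edge(ra, rb, weight=data["weight"])
    if C.number_of_edges() == 0:
        return [groups[r] for r in C.nodes]
    lam, _ = nx.stoer_wagner(C, weight="weight")
    # an edge lies in some minimum cut iff the minimum cut separating its
    # endpoints is no heavier than the global minimum cut
    drop = []
    for a, b in C.edges:
        st_cut = nx.minimum_cut_value(C, a, b, capacity="weight")
        if st_cut <= lam + 1e-12:
            drop.append((a, b))
    C.remove_edges_from(drop)
    comps = []
    for comp in nx.connected_components(C):
        out: set = set()
        for r in comp:
            out |= groups[r]
        comps.append(out)
    return comps


# ---------------------------------------------------------------------------
# STEAC and STAR


def _check_gene_trees(gene_trees: Sequence[dendropy.Tree], species: Sequence[str]):
    want = set(species)
    for t in gene_trees:
        have = set(leaf_labels(t))
        if have != want:
            raise ValueError(
                f"gene tree leaf set {sorted(have)} != species {sorted(want)}"
            )


def mean_coalescence_times(
    gene_trees: Sequence[dendropy.Tree]
) -> SpeciesDistanceMatrix:
    """Pairwise coalescence times -- half the leaf-to-leaf path length --
    averaged over gene trees."""
    if not gene_trees:
        raise ValueError("no gene trees")
    species = sorted(leaf_labels(gene_trees[0]))
    _check_gene_trees(gene_trees, species)
    k = len(species)
    acc = np.zeros((k, k))
    for t in gene_trees:
        for e in t.preorder_edge_iter():
            if e.tail_node is not None and e.length is None:
                raise ValueError("STEAC needs branch lengths on gene trees")
        pdm = t.phylogenetic_distance_matrix()
        taxa = {x.label: x for x in t.taxon_namespace}
        for i, j in itertools.combinations(range(k), 2):
            d = pdm.patristic_distance(taxa[species[i]], taxa[species[j]]) / 2.0
            acc[i, j] += d
            acc[j, i] += d
    acc /= len(gene_trees)
    return SpeciesDistanceMatrix(species, acc, "pooled")


def steac_estimate(
    gene_trees: Sequence[dendropy.Tree], outgroup: str
) -> dendropy.Tree:
    """STEAC: NJ on mean pairwise coalescence times, rooted and pruned."""
    nj = genetrees.neighbor_joining(mean_coalescence_times(gene_trees))
    return _root_and_prune(nj, outgroup)


def _rank_matrix(tree: dendropy.Tree, species: Sequence[str]) -> np.ndarray:
    """STAR coalescence ranks: root rank = number of species; every internal
    node ranks one less than its immediate ancestor; a pair's entry is the
    rank of its connecting node."""
    k = len(species)
    idx = {s: i for i, s in enumerate(species)}
    rank: Dict[dendropy.Node, int] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if node.parent_node is None:
            rank[node] = k
        else:
            rank[node] = rank[node.parent_node] - 1
    out = np.zeros((k, k))
    below: Dict[dendropy.Node, List[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = [idx[node.taxon.label]]
            continue
        kids = [below[c] for c in node.child_nodes()]
        for g1, g2 in itertools.combinations(kids, 2):
            for i in g1:
                for j in g2:
                    out[i, j] = out[j, i] = rank[node]
        merged: List[int] = []
        for g in kids:
            merged.extend(g)
        below[node] = merged
    return out


def star_estimate(
    gene_trees: Sequence[dendropy.Tree], outgroup: str
) -> dendropy.Tree:
    """STAR: NJ on average coalescence ranks, rooted and pruned."""
    if not gene_trees:
        raise ValueError("no gene trees")
    species = sorted(leaf_labels(gene_trees[0]))
    _check_gene_trees(gene_trees, species)
    acc = np.zeros((len(species), len(species)))
    for t in gene_trees:
        if not t.is_rooted:
            raise ValueError("STAR needs rooted gene trees")
        acc += _rank_matrix(t, species)
    acc /= len(gene_trees)
    nj = genetrees.neighbor_joining(SpeciesDistanceMatrix(species, acc, "pooled"))
    return _root_and_prune(nj, outgroup)


# ---------------------------------------------------------------------------
# rooted triples and RTC


def extract_rooted_triples(
    tree: dendropy.Tree, ingroup: Optional[Sequence[str]] = None
) -> List[RootedTriple]:
    """All rooted triples displayed by a rooted tree (restricted to the
    ingroup); unresolved restrictions emit nothing."""
    if not tree.is_rooted:
        raise ValueError("need a rooted tree")
    labs = sorted(ingroup) if ingroup is not None else sorted(leaf_labels(tree))
    labs = [l for l in labs if l in set(leaf_labels(tree))]
    masks = clade_masks(tree, labs, nontrivial_only=False)
    full = (1 << len(labs)) - 1
    # smallest clade containing each pair
    pair_lca = {}
    ordered = sorted(masks | {full}, key=lambda m: bin(m).count("1"))
    for i, j in itertools.combinations(range(len(labs)), 2):
        want = (1 << i) | (1 << j)
        for m in ordered:
            if m & want == want:
                pair_lca[(i, j)] = m
                break
    triples = []
    for a, b, c in itertools.combinations(range(len(labs)), 3):
        options = [
            ((a, b), c), ((a, c), b), ((b, c), a),
        ]
        resolved = [
            (pair, out) for pair, out in options
            if not pair_lca[pair] >> out & 1
        ]
        if len(resolved) == 1:
            (i, j), o = resolved[0]
            triples.append(
                RootedTriple(frozenset({labs[i], labs[j]}), labs[o])
            )
    return triples


def _pool_triples(tree_triples: Iterable[List[RootedTriple]]) -> Dict[Tuple[FrozenSet[str], str], float]:
    pooled: Dict[Tuple[FrozenSet[str], str], float] = {}
    for triples in tree_triples:
        for t in triples:
            key = (t.pair, t.outlier)
            pooled[key] = pooled.get(key, 0.0) + t.weight
    return pooled


def _puzzle_once(
    labels: Sequence[str],
    pooled: Mapping[Tuple[FrozenSet[str], str], float],
    order: Sequence[int],
    rng: np.random.Generator,
) -> FrozenSet[int]:
    """One triplet-puzzling insertion pass; returns the clade-mask set."""
    def w(i, j, o):
        return pooled.get((frozenset({labels[i], labels[j]}), labels[o]), 0.0)

    a, b, c = order[0], order[1], order[2]
    opts = [
        (w(a, b, c), frozenset({(1 << a) | (1 << b)})),
        (w(a, c, b), frozenset({(1 << a) | (1 << c)})),
        (w(b, c, a), frozenset({(1 << b) | (1 << c)})),
    ]
    mx = max(o[0] for o in opts)
    best = [o[1] for o in opts if o[0] >= mx - 1e-12]
    clusters = set(best[rng.integers(len(best))] if len(best) > 1 else best[0])
    inserted = [a, b, c]
    root = (1 << a) | (1 << b) | (1 << c)
    clusters.add(root)

    for x in order[3:]:
        xbit = 1 << x
        candidates = list(clusters) + [1 << t for t in inserted]
        scored = []
        for cand in candidates:
            new_clusters = {
                (cl | xbit) if (cl & cand) == cand and cl != cand else cl
                for cl in clusters
            }
            new_clusters.add(cand | xbit)
            score = 0.0
            for t, u in itertools.combinations(inserted, 2):
                # resolution of {x, t, u} on the candidate tree
                res = _resolve_triple(new_clusters, x, t, u)
                if res is not None:
                    score += w(*res)
            scored.append((score, new_clusters))
        mx = max(s for s, _ in scored)
        ties = [cl for s, cl in scored if s >= mx - 1e-12]
        clusters = ties[rng.integers(len(ties))] if len(ties) > 1 else ties[0]
        inserted.append(x)
    full = 0
    for t in inserted:
        full |= 1 << t
    return frozenset(m for m in clusters if m != full and bin(m).count("1") >= 2)


def _resolve_triple(clusters, x, t, u):
    trip = (1 << x) | (1 << t) | (1 << u)
    best = None
    best_size = None
    for cl in clusters:
        inter = cl & trip
        if bin(inter).count("1") == 2:
            size = bin(cl).count("1")
            if best_size is None or size < best_size:
                best, best_size = inter, size
    if best is None:
        return None
    pair = [i for i in (x, t, u) if best >> i & 1]
    (out,) = [i for i in (x, t, u) if not best >> i & 1]
    return pair[0], pair[1], out


def rtc_estimate(
    gene_trees: Sequence[dendropy.Tree],
    rng: np.random.Generator,
    puzzling_orders: int = 100,
) -> dendropy.Tree:
    """Rooted Triple Consensus: pool the displayed rooted triples of all gene
    trees and apply triplet puzzling with random insertion orders; the
    majority-rule consensus of the puzzled trees is returned (rooted)."""
    if not gene_trees:
        raise ValueError("no gene trees")
    labels = sorted(leaf_labels(gene_trees[0]))
    pooled = _pool_triples(extract_rooted_triples(t, labels) for t in gene_trees)
    counts: Dict[int, int] = {}
    for _ in range(puzzling_orders):
        order = list(rng.permutation(len(labels)))
        masks = _puzzle_once(labels, pooled, order, rng)
        for m in masks:
            counts[m] = counts.get(m, 0) + 1
    majority = {m for m, c in counts.items() if c > puzzling_orders / 2}
    return tree_from_clades(majority, labels)


# ---------------------------------------------------------------------------
# MDC


def _cluster_masks_rooted(tree: dendropy.Tree, labels: Sequence[str]) -> List[int]:
    """All internal-node clusters (including the root) as bitmasks."""
    idx = {lab: i for i, lab in enumerate(labels)}
    out = []
    mask: Dict[dendropy.Node, int] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            mask[node] = 1 << idx[node.taxon.label]
        else:
            m = 0
            for c in node.child_nodes():
                m |= mask[c]
            mask[node] = m
            out.append(m)
    return out


def count_extra_lineages(
    gene_tree: dendropy.Tree, species_tree: dendropy.Tree
) -> int:
    """Deep-coalescence cost of fitting one gene tree into a species tree.

    For every species-tree branch, the number of gene lineages exiting the
    branch under the most parsimonious embedding, minus one, summed over
    branches.  Leaf sets must match one-to-one.
    """
    labs = sorted(leaf_labels(species_tree))
    if sorted(leaf_labels(gene_tree)) != labs:
        raise ValueError("gene and species trees must share a leaf set")
    gmasks = _cluster_masks_rooted(gene_tree, labs)
    full = (1 << len(labs)) - 1
    cost = 0
    for A in _cluster_masks_rooted(species_tree, labs):
        if A == full:
            continue  # no branch above the root
        coal = sum(1 for g in gmasks if g & ~A == 0)
        cost += bin(A).count("1") - coal - 1
    return cost


@functools.lru_cache(maxsize=4)
def enumerate_rooted_topologies(m: int) -> Tuple[np.ndarray, np.ndarray]:
    """All (2m-3)!! rooted binary topologies on ``m`` labeled leaves.

    Returns ``(clusters, base)``: an array of the m-2 non-root internal
    cluster masks per topology and the per-topology sum of (cluster size - 1).
    """
    if m < 2:
        raise ValueError("need >= 2 leaves")
    trees: List[FrozenSet[int]] = [frozenset({(1 << 0) | (1 << 1)})]
    for x in range(2, m):
        xbit = 1 << x
        new: List[FrozenSet[int]] = []
        for clusters in trees:
            nodes = list(clusters) + [1 << t for t in range(x)]
            for cand in nodes:
                nc = frozenset(
                    (cl | xbit) if (cl & cand) == cand and cl != cand else cl
                    for cl in clusters
                ) | {cand | xbit}
                new.append(nc)
        trees = new
    full = (1 << m) - 1
    rows = []
    for clusters in trees:
        row = sorted(cl for cl in clusters if cl != full)
        rows.append(row)
    clusters_arr = np.asarray(rows, dtype=np.int64)
    sizes = np.zeros(clusters_arr.shape, dtype=np.int64)
    for b in range(m):
        sizes += (clusters_arr >> b) & 1
    base = (sizes - 1).sum(axis=1)
    return clusters_arr, base


def _subset_sums(counts: np.ndarray, m: int) -> np.ndarray:
    """Sum-over-subsets transform: z[A] = sum_{g subset of A} counts[g]."""
    z = counts.astype(np.int64).copy()
    for b in range(m):
        bit = 1 << b
        idx = np.arange(1 << m)
        has = (idx & bit).astype(bool)
        z[has] += z[idx[has] ^ bit]
    return z


def mdc_estimate(
    gene_trees: Sequence[dendropy.Tree],
    rng: np.random.Generator,
    mode: str = "exact",
    exact_limit: int = 8,
) -> dendropy.Tree:
    """Minimize-deep-coalescences species tree.

    ``exact`` enumerates every rooted binary topology (feasible to eight
    taxa); ``heuristic`` runs rooted-NNI descent from a randomly refined
    greedy consensus of the gene-tree clades.  Co-optimal topologies are
    drawn uniformly from the seeded stream.
    """
    if not gene_trees:
        raise ValueError("no gene trees")
    labs = sorted(leaf_labels(gene_trees[0]))
    m = len(labs)
    counts = np.zeros(1 << m, dtype=np.int64)
    L = len(gene_trees)
    for t in gene_trees:
        if sorted(leaf_labels(t)) != labs:
            raise ValueError("gene trees must share a leaf set")
        for g in _cluster_masks_rooted(t, labs):
            counts[g] += 1
    z = _subset_sums(counts, m)

    if mode == "exact" and m <= exact_limit:
        clusters_arr, base = enumerate_rooted_topologies(m)
        costs = base * L - z[clusters_arr].sum(axis=1)
        best = costs.min()
        opt = np.flatnonzero(costs == best)
        pick = opt[rng.integers(len(opt))] if len(opt) > 1 else opt[0]
        masks = {int(cl) for cl in clusters_arr[pick]}
        return tree_from_clades(masks, labs)

    # heuristic: NNI descent from a refined greedy consensus
    clade_counts = {
        int(mask): int(counts[mask])
        for mask in np.flatnonzero(counts)
        if bin(int(mask)).count("1") >= 2 and int(mask) != (1 << m) - 1
    }
    start = greedy_consensus(clade_counts, labs)
    clusters = set(clade_masks(start, labs))
    clusters = _refine_random(clusters, m, rng)

    def cost_of(cl_set) -> int:
        arr = np.fromiter(cl_set, dtype=np.int64)
        sizes = np.zeros(len(arr), dtype=np.int64)
        for b in range(m):
            sizes += (arr >> b) & 1
        return int((sizes - 1).sum() * L - z[arr].sum())

    cur = frozenset(clusters)
    cur_cost = cost_of(cur)
    improved = True
    while improved:
        improved = False
        neighbors = list(_rooted_nni(cur, m))
        rng.shuffle(neighbors)
        for cand in neighbors:
            c = cost_of(cand)
            if c < cur_cost:
                cur, cur_cost = cand, c
                improved = True
                break
    return tree_from_clades(set(cur), labs)


def _refine_random(clusters: set, m: int, rng: np.random.Generator) -> set:
    """Randomly refine a (possibly polytomous) rooted cluster set to binary."""
    full = (1 << m) - 1
    work = set(clusters)
    changed = True
    while changed:
        changed = False
        for parent in sorted(work | {full}, key=lambda x: bin(x).count("1")):
            kids = _children(work, parent, m)
            if len(kids) > 2:
                i, j = rng.choice(len(kids), size=2, replace=False)
                work.add(kids[i] | kids[j])
                changed = True
                break
    return work


def _children(clusters: set, parent: int, m: int) -> List[int]:
    inside = [c for c in clusters if c != parent and (c & parent) == c]
    maximal = [
        c for c in inside
        if not any(d != c and (c & d) == c for d in inside)
    ]
    covered = 0
    for c in maximal:
        covered |= c
    kids = list(maximal)
    for b in range(m):
        bit = 1 << b
        if parent & bit and not covered & bit:
            kids.append(bit)
    return kids


def _rooted_nni(clusters: FrozenSet[int], m: int) -> Iterable[FrozenSet[int]]:
    """Rooted NNI neighborhood on a binary cluster set."""
    full = (1 << m) - 1
    allc = set(clusters) | {full}
    for c in clusters:
        supers = [d for d in allc if d != c and (c & d) == c]
        parent = min(supers, key=lambda d: bin(d).count("1"))
        sibs = [
            k for k in _children(set(clusters), parent, m)
            if k != c and (k & c) == 0
        ]
        kids = _children(set(clusters), c, m)
        for s in sibs:
            for a in kids:
                newc = (c & ~a) | s
                if bin(newc).count("1") < 2:
                    continue
                cand = (set(clusters) - {c}) | {newc}
                cand = {x for x in cand if 2 <= bin(x).count("1") and x != full}
                yield frozenset(cand)


# ---------------------------------------------------------------------------
# greedy consensus


def greedy_consensus(
    clade_counts: Mapping[int, float], labels: Sequence[str]
) -> dendropy.Tree:
    """Accept clades in decreasing count order whenever compatible with the
    clades accepted so far; ties broken by smaller bitmask (deterministic)."""
    accepted: List[int] = []
    supports: Dict[int, float] = {}
    for mask, cnt in sorted(clade_counts.items(), key=lambda kv: (-kv[1], kv[0])):
        if all(compatible(mask, a) for a in accepted):
            accepted.append(mask)
            supports[mask] = cnt
    return tree_from_clades(accepted, labels, branch_support=supports)
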