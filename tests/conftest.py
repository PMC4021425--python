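import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from treestrat.io import LocusAlignment, MultilocusDataset, SequenceRecord

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_locus(seqs, locus_id="l1", species=None):
    """Alignment from {individual: residues}; species defaults to the
    individual id (one individual per species)."""
    records = [
        SequenceRecord(ind, (species or {}).get(ind, ind), locus_id, s)
        for ind, s in seqs.items()
    ]
    return LocusAlignment(locus_id, records)


def make_dataset(loci, species_map, ingroup, outgroups):
    return MultilocusDataset(
        loci, species_map, list(ingroup) + list(outgroups), len(ingroup)
    )


@pytest.fixture(scope="session")
def pine_small():
    from treestrat.simulate import generate_pine_like_dataset

    dataset, truth = generate_pine_like_dataset("pine_small", 7)
    return dataset, truth


@pytest.fixture(scope="session")
def pine_small_roles(pine_small):
    from treestrat.datasets import build_all_roles

    dataset, _ = pine_small
    return build_all_roles(dataset, np.random.default_rng(3))


def random_rooted_tree(rng, labels):
    """Rooted binary tree via random sequential joins."""
    from treestrat.trees import read_newick

    nodes = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})")
    return read_newick(nodes[0] + ";")


def enumerate_unrooted(labels):
    """Independent enumeration of unrooted topologies as newick strings."""
    def build(partial, remaining):
        if not remaining:
            yield partial
            return
        x, rest = remaining[0], remaining[1:]
        for i, _ in enumerate(_spots(partial)):
            yield from build(_attach(partial, i, x), rest)

    def _spots(node, prefix=()):
        out = []
        if isinstance(node, tuple):
            for k, ch in enumerate(node):
                out.append(prefix + (k,))
                out.extend(_spots(ch, prefix + (k,)))
        return out

    def _attach(node, idx, x):
        path = _spots(node)[idx]

        def go(nd, p):
            if not p:
                return (nd, x)
            k = p[0]
            return tuple(go(c, p[1:]) if i == k else c for i, c in enumerate(nd))
        return go(node, path)

    def render(nd):
        if isinstance(nd, tuple):
            return "(" + ",".join(render(c) for c in nd) + ")"
        return nd

    start = (labels[0], labels[1], labels[2])
    for t in build(start, labels[3:]):
        yield render(t) + ";"


def random_dataset(rng, n_species=4, n_ind=2, n_loci=6, length=30,
                   n_outgroup=1, p_gap=0.15, alphabet="ACGT"):
    """Small random dataset; sequences are low-diversity so zero-distance
    pairs occur and the Ds0/Dp0 filters actually bite."""
    species = [f"s{i}" for i in range(n_species)]
    smap = {}
    loci = []
    for l in range(n_loci):
        recs = {}
        base = "".join(rng.choice(list(alphabet), size=length))
        for sp in species:
            for j in range(n_ind):
                ind = f"{sp}_i{j}"
                smap[ind] = sp
                seq = list(base)
                for pos in range(length):
                    r = rng.random()
                    if r < p_gap:
                        seq[pos] = "-" if rng.random() < 0.5 else "?"
                    elif r < p_gap + 0.08:
                        seq[pos] = alphabet[rng.integers(4)]
                recs[ind] = "".join(seq)
        loci.append(make_locus(recs, f"loc{l}", species=smap))
    return make_dataset(loci, smap, species[: n_species - n_outgroup],
                        species[n_species - n_outgroup:])


def splits(tree):
    """Unrooted split set of a tree (smaller-side bitmasks over sorted labels)."""
    from treestrat.trees import clade_masks, leaf_labels

    labs = sorted(leaf_labels(tree))
    n = len(labs)
    full = (1 << n) - 1
    out = set()
    for m in clade_masks(tree, labs):
        k = bin(m).count("1")
        if 2 <= k <= n - 2:
            out.add(min(m, full ^ m))
    return labs, out


def random_additive_matrix(rng, n):
    """Distances induced by a random binary tree with positive lengths."""
    import itertools

    import dendropy

    from treestrat.distances import SpeciesDistanceMatrix

    taxa = [f"t{i}" for i in range(n)]
    rng.shuffle(taxa)
    tree = dendropy.Tree.get(data=f"({taxa[0]}:0,{taxa[1]}:0);", schema="newick")
    for lab in taxa[2:]:
        edges = [e for e in tree.preorder_edge_iter() if e.tail_node is not None]
        e = edges[rng.integers(len(edges))]
        mid = dendropy.Node()
        par, child = e.tail_node, e.head_node
        par.remove_child(child)
        par.add_child(mid)
        mid.add_child(child)
        mid.add_child(dendropy.Node(taxon=tree.taxon_namespace.new_taxon(lab)))
    for e in tree.preorder_edge_iter():
        if e.tail_node is not None:
            e.length = float(rng.uniform(0.5, 2.0))
    tree.is_rooted = False
    labs = sorted(t.label for t in tree.taxon_namespace)
    pdm = tree.phylogenetic_distance_matrix()
    tx = {t.label: t for t in tree.taxon_namespace}
    vals = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        vals[i, j] = vals[j, i] = pdm.patristic_distance(tx[labs[i]], tx[labs[j]])
    return tree, SpeciesDistanceMatrix(labs, vals, "pooled")


def oracle_extra_lineages(gene, species_tree):
    """Independent deep-coalescence count via MRCA mapping: each gene-tree
    coalescence maps to the species-tree MRCA population of its leaf set;
    lineages exiting a species branch = leaves below it minus coalescences
    mapped at or below it."""
    from treestrat.trees import leaf_labels

    labs = sorted(leaf_labels(species_tree))
    node_mask = {}
    idx = {l: i for i, l in enumerate(labs)}
    for node in species_tree.postorder_node_iter():
        if node.is_leaf():
            node_mask[node] = 1 << idx[node.taxon.label]
        else:
            node_mask[node] = sum(node_mask[c] for c in node.child_nodes())
    full = (1 << len(labs)) - 1

    def sp_mrca_mask(mask):
        best = full
        for node, m in node_mask.items():
            if mask & m == mask and bin(m).count("1") < bin(best).count("1"):
                best = m
        return best

    gene_coal = []
    gmask = {}
    for node in gene.postorder_node_iter():
        if node.is_leaf():
            gmask[node] = 1 << idx[node.taxon.label]
        else:
            gmask[node] = sum(gmask[c] for c in node.child_nodes())
            gene_coal.append(sp_mrca_mask(gmask[node]))
    cost = 0
    for node, m in node_mask.items():
        if node.is_leaf() or m == full:
            continue
        coal_below = sum(1 for c in gene_coal if c & m == c)
        cost += bin(m).count("1") - coal_below - 1
    return cost


def all_rooted_topologies(labels):
    """Independent enumeration: every unrooted shape rooted on every edge."""
    from treestrat.trees import clade_masks, read_newick

    seen = set()
    labs = sorted(labels)
    for nwk in enumerate_unrooted(list(labels)):
        un = read_newick(nwk)
        un.is_rooted = False
        for edge in list(un.preorder_edge_iter()):
            if edge.tail_node is None:
                continue
            work = un.clone(depth=1)
            want = None
            m1 = sum(1 << labs.index(l.taxon.label)
                     for l in edge.head_node.leaf_iter())
            for e2 in work.preorder_edge_iter():
                if e2.tail_node is None:
                    continue
                m2 = sum(1 << labs.index(l.taxon.label)
                         for l in e2.head_node.leaf_iter())
                if m1 == m2:
                    want = e2
                    break
            work.reroot_at_edge(want, update_bipartitions=False)
            work.is_rooted = True
            key = clade_masks(work, labs)
            if key not in seen:
                seen.add(key)
                yield work
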