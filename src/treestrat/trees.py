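"""Tree utilities shared across the pipeline.

Trees cross module boundaries as :class:`dendropy.Tree` objects.  Internally
most species-tree algorithms work on *clade bitmasks*: given an ordered label
list, each clade of a rooted tree is the integer whose set bits mark the member
taxa.  A rooted topology is then just a frozenset of masks, which makes clade
accounting, compatibility checks and Robinson-Foulds comparisons cheap.
"""

from __future__ import annotations

from typing import Dict, FrozenSet, Iterable, List, Mapping, Sequence

import dendropy

__all__ = [
    "read_newick",
    "write_newick",
    "leaf_labels",
    "clade_masks",
    "tree_from_clades",
    "robinson_foulds",
    "root_with_outgroup",
    "is_rooted",
]


class NewickError(ValueError):
    """Malformed Newick input (unbalanced parentheses, duplicate labels...)."""


def _taxon_namespace(labels: Iterable[str]) -> dendropy.TaxonNamespace:
    return dendropy.TaxonNamespace(list(labels))


def read_newick(text: str) -> dendropy.Tree:
    """Parse a single Newick tree from a string.

    Rootedness follows the basal degree: a basal bifurcation is read as a
    rooted tree, a basal multifurcation as unrooted.  Duplicate leaf labels
    are rejected.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickError(f"could not parse Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise NewickError("duplicate leaf labels in Newick input")
    nchild = len(tree.seed_node.child_nodes())
    tree.is_rooted = nchild == 2
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize one tree per line; branch lengths kept to 12 significant digits."""
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".12g",
        unquoted_underscores=True,
    )
    return s.strip() + "\n"


def leaf_labels(tree: dendropy.Tree) -> List[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def is_rooted(tree: dendropy.Tree) -> bool:
    return bool(tree.is_rooted)


def clade_masks(
    tree: dendropy.Tree,
    labels: Sequence[str],
    nontrivial_only: bool = True,
) -> FrozenSet[int]:
    """Clade bitmask set of a rooted tree restricted to ``labels``.

    Leaves outside ``labels`` are ignored.  With ``nontrivial_only`` the
    singletons and the full set are excluded (a clade is non-trivial iff
    1 < size < n).
    """
    index = {lab: i for i, lab in enumerate(labels)}
    full = (1 << len(labels)) - 1
    masks = set()
    node_mask: Dict[dendropy.Node, int] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            lab = node.taxon.label
            node_mask[node] = 1 << index[lab] if lab in index else 0
        else:
            m = 0
            for ch in node.child_nodes():
                m |= node_mask[ch]
            node_mask[node] = m
            if m:
                masks.add(m)
    if nontrivial_only:
        masks = {m for m in masks if m != full and bin(m).count("1") >= 2}
    return frozenset(masks)


def mask_to_labels(mask: int, labels: Sequence[str]) -> List[str]:
    return [lab for i, lab in enumerate(labels) if mask >> i & 1]


def compatible(a: int, b: int) -> bool:
    """Two clades are compatible iff nested or disjoint."""
    inter = a & b
    return inter == 0 or inter == a or inter == b


def tree_from_clades(
    masks: Iterable[int],
    labels: Sequence[str],
    branch_support: Mapping[int, float] | None = None,
) -> dendropy.Tree:
    """Build the rooted (possibly polytomous) tree realizing a compatible clade set.

    ``branch_support`` optionally annotates accepted clades (stored as node
    labels) -- used for consensus trees with support values.
    """
    n = len(labels)
    full = (1 << n) - 1
    mset = {m for m in masks if 2 <= bin(m).count("1") and m != full}
    for a in mset:
        for b in mset:
            if not compatible(a, b):
                raise ValueError("incompatible clade set")
    tns = _taxon_namespace(labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True

    ordered = sorted(mset | {full}, key=lambda m: -bin(m).count("1"))
    nodes: Dict[int, dendropy.Node] = {}
    nodes[full] = tree.seed_node
    parent_of: Dict[int, int] = {}
    for m in ordered:
        if m == full:
            continue
        # smallest strict superset already materialized
        best = full
        for cand in ordered:
            if cand != m and (cand & m) == m and bin(cand).count("1") < bin(best).count("1"):
                best = cand
        parent_of[m] = best
        node = dendropy.Node()
        if branch_support is not None and m in branch_support:
            node.label = f"{branch_support[m]:g}"
        nodes[m] = node
    for m, p in parent_of.items():
        nodes[p].add_child(nodes[m])
    # attach leaves under the smallest containing clade
    for i, lab in enumerate(labels):
        bit = 1 << i
        best = full
        for m in ordered:
            if m != full and (m & bit) and bin(m).count("1") < bin(best).count("1"):
                best = m
        leaf = dendropy.Node(taxon=tns.get_taxon(lab))
        nodes[best].add_child(leaf)
    return tree


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Rooted Robinson-Foulds distance: |clades(t1) XOR clades(t2)| over
    non-trivial clades.  Leaf sets must agree."""
    l1, l2 = sorted(leaf_labels(t1)), sorted(leaf_labels(t2))
    if l1 != l2:
        raise ValueError("trees have different leaf sets")
    c1 = clade_masks(t1, l1)
    c2 = clade_masks(t2, l1)
    return len(c1 ^ c2)


def rf_between_masks(c1: FrozenSet[int], c2: FrozenSet[int]) -> int:
    return len(c1 ^ c2)


def root_with_outgroup(
    tree: dendropy.Tree, outgroup: str, prune_outgroup: bool = False
) -> dendropy.Tree:
    """Root on the branch subtending the outgroup leaf; optionally prune it.

    Returns a new tree; the input is left untouched.
    """
    work = tree.clone(depth=1)
    og = None
    for leaf in work.leaf_node_iter():
        if leaf.taxon.label == outgroup:
            og = leaf
            break
    if og is None:
        raise ValueError(f"outgroup {outgroup!r} is not a leaf of the tree")
    edge = og.edge
    if edge.length is None:
        work.to_outgroup_position(og, update_bipartitions=False)
    else:
        work.reroot_at_edge(edge, length1=edge.length / 2.0, length2=edge.length / 2.0,
                            update_bipartitions=False)
    work.is_rooted = True
    if prune_outgroup:
        work.prune_taxa_with_labels([outgroup])
        # pruning may leave a unifurcation at the root
        work.suppress_unifurcations()
        work.is_rooted = True
    return work
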