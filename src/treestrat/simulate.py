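"""Synthetic multilocus data under the multispecies coalescent.

Gene trees are simulated branch-by-branch down a species tree whose edge
lengths are in coalescent units (generations / 2N): within each species-tree
branch, ``j`` lineages coalesce with exponential waiting times at rate
``C(j, 2)`` per unit, and surviving lineages pass to the parent branch.
Sequences evolve along the gene tree under a reversible substitution model; a
single scale factor converts coalescent units to expected substitutions per
site, so the amount of incomplete lineage sorting and the sequence divergence
are independently tunable.

The ``pine_full`` preset emulates the structure of a multilocus conifer study:
11 species (8 ingroup forming a clade, 3 deep outgroups), ~120 individuals,
121 loci of ~390 bp (~47 kb in total) and per-individual missing loci.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import dendropy
import numpy as np

from .io import LocusAlignment, MultilocusDataset, SequenceRecord
from .submodel import NUCLEOTIDES, SubstitutionModel, hky_model
from .trees import read_newick

__all__ = [
    "MSCModel",
    "SimulatedTruth",
    "simulate_msc_gene_tree",
    "simulate_alignment",
    "apply_missingness",
    "generate_pine_like_dataset",
    "PRESETS",
]


@dataclass
class MSCModel:
    """Study-design description for the simulator.

    ``species_tree`` carries branch lengths in coalescent units; ``scale``
    converts one coalescent unit into expected substitutions per site.
    """

    species_tree: dendropy.Tree
    samples_per_species: Dict[str, int]
    locus_count: int = 1
    locus_length: int = 500
    substitution_model: SubstitutionModel = field(default_factory=hky_model)
    scale: float = 0.01
    rate_sigma: float = 0.0  # lognormal sd of the per-locus rate multiplier
    missingness: float = 0.0

    def __post_init__(self) -> None:
        for sp, k in self.samples_per_species.items():
            if k < 1:
                raise ValueError(f"samples_per_species[{sp!r}] must be >= 1")
        if not (0.0 <= self.missingness < 1.0):
            raise ValueError("missingness must lie in [0, 1)")
        for edge in self.species_tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError("species-tree branch lengths must be >= 0")


@dataclass
class SimulatedTruth:
    """The generating species tree plus per-locus gene trees and alignments."""

    species_tree: dendropy.Tree
    gene_trees: List[dendropy.Tree]
    alignments: List[LocusAlignment]


def _node_ages(tree: dendropy.Tree) -> Dict[dendropy.Node, float]:
    """Ages above the leaves (leaves at age 0); requires an ultrametric tree."""
    ages: Dict[dendropy.Node, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            ages[node] = 0.0
        else:
            cand = [ages[c] + (c.edge.length or 0.0) for c in node.child_nodes()]
            if max(cand) - min(cand) > 1e-6 * max(1.0, max(cand)):
                raise ValueError("species tree must be ultrametric")
            ages[node] = float(np.mean(cand))
    return ages


class _Lineage:
    __slots__ = ("node", "time")

    def __init__(self, node: dendropy.Node, time: float):
        self.node = node
        self.time = time


def simulate_msc_gene_tree(model: MSCModel, rng: np.random.Generator) -> dendropy.Tree:
    """One rooted binary gene tree under the multispecies coalescent.

    Leaf labels are individual ids ``<species>_<i>``; edge lengths are in
    coalescent units.  Node ages are recorded in ``node.age``.
    """
    sp_tree = model.species_tree
    ages = _node_ages(sp_tree)
    taxa = dendropy.TaxonNamespace()
    active: Dict[dendropy.Node, List[_Lineage]] = {}

    def coalesce(pool: List[_Lineage], t0: float, t1: float) -> List[_Lineage]:
        t = t0
        while len(pool) > 1:
            j = len(pool)
            t += rng.exponential(1.0 / (j * (j - 1) / 2.0))
            if t >= t1:
                break
            i, k = rng.choice(j, size=2, replace=False)
            a, b = pool[i], pool[k]
            parent = dendropy.Node()
            parent.age = t
            parent.add_child(a.node)
            parent.add_child(b.node)
            a.node.edge.length = t - a.time
            b.node.edge.length = t - b.time
            pool = [l for m, l in enumerate(pool) if m not in (i, k)]
            pool.append(_Lineage(parent, t))
        return pool

    for node in sp_tree.postorder_node_iter():
        if node.is_leaf():
            sp = node.taxon.label
            pool = []
            for i in range(model.samples_per_species.get(sp, 1)):
                leaf = dendropy.Node(taxon=taxa.new_taxon(f"{sp}_{i + 1}"))
                leaf.age = 0.0
                pool.append(_Lineage(leaf, 0.0))
        else:
            pool = []
            for child in node.child_nodes():
                pool.extend(active.pop(child))
        if node.parent_node is None:
            pool = coalesce(pool, ages[node], np.inf)
        else:
            # lineage times stay at their node ages so that edge lengths
            # accumulate across species-branch boundaries
            pool = coalesce(pool, ages[node], ages[node.parent_node])
        active[node] = pool

    (root_lineage,) = active[sp_tree.seed_node]
    gene = dendropy.Tree(taxon_namespace=taxa)
    gene.seed_node = root_lineage.node
    gene.seed_node.edge.length = None
    gene.is_rooted = True
    return gene


def _evolve(parent_states: np.ndarray, P: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    cum = P.cumsum(axis=1)
    u = rng.random(parent_states.shape[0])
    return (u[:, None] > cum[parent_states]).sum(axis=1).astype(np.int8)


def simulate_alignment(
    tree: dendropy.Tree,
    model: MSCModel,
    rng: np.random.Generator,
    locus_id: str = "locus",
    rate_multiplier: float = 1.0,
) -> LocusAlignment:
    """Finite-sites simulation down a gene tree.

    The root sequence is drawn from the stationary frequencies; each branch
    applies ``P(scale * rate_multiplier * length)``; columns are independent.
    """
    sub = model.substitution_model
    L = model.locus_length
    states: Dict[dendropy.Node, np.ndarray] = {}
    root_states = rng.choice(4, size=L, p=sub.freqs).astype(np.int8)
    states[tree.seed_node] = root_states
    records: List[SequenceRecord] = []
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            t = (node.edge.length or 0.0) * model.scale * rate_multiplier
            if t == 0.0:
                states[node] = states[node.parent_node]
            else:
                P = sub.transition_matrix(t)
                states[node] = _evolve(states[node.parent_node], P, rng)
        if node.is_leaf():
            seq = "".join(NUCLEOTIDES[s] for s in states[node])
            ind = node.taxon.label
            species = ind.rsplit("_", 1)[0]
            records.append(SequenceRecord(ind, species, locus_id, seq))
    records.sort(key=lambda r: r.individual_id)
    return LocusAlignment(locus_id, records)


def apply_missingness(
    dataset: MultilocusDataset, rate: float, rng: np.random.Generator
) -> MultilocusDataset:
    """Delete each (individual, locus) record independently with probability
    ``rate``, re-drawing deletions that would leave a species without data at
    a locus."""
    if not (0.0 <= rate < 1.0):
        raise ValueError("rate must lie in [0, 1)")
    if rate == 0.0:
        return dataset
    new_loci: List[LocusAlignment] = []
    for loc in dataset.loci:
        by_sp = dataset.individuals_by_species(loc)
        keep: Dict[str, bool] = {}
        for sp, inds in by_sp.items():
            if not inds:
                continue
            while True:
                flags = rng.random(len(inds)) >= rate
                if flags.any():
                    break
            for ind, f in zip(inds, flags):
                keep[ind] = bool(f)
        recs = [r for r in loc.records if keep.get(r.individual_id, True)]
        new_loci.append(LocusAlignment(loc.locus_id, recs))
    return MultilocusDataset(
        new_loci, dict(dataset.species_map), list(dataset.species), dataset.n_ingroup
    )


# ---------------------------------------------------------------------------
# presets

# Eight ingroup species in a balanced clade (internal branches 0.4 coalescent
# units -- substantial incomplete lineage sorting) with the three outgroups
# forming the sister clade at a deep divergence.
_PINE_TREE = (
    "((((sp1:1,sp2:1):0.4,(sp3:1,sp4:1):0.4):0.4,"
    "((sp5:1,sp6:1):0.4,(sp7:1,sp8:1):0.4):0.4):10.2,"
    "((out1:1,out2:1):1,out3:2):10);"
)

# Same ingroup shape with very short internal branches (<=0.5 units) and one
# deep outgroup: a high-discordance regime.
_HIGH_ILS_TREE = (
    "((((sp1:1,sp2:1):0.15,(sp3:1,sp4:1):0.15):0.15,"
    "((sp5:1,sp6:1):0.15,(sp7:1,sp8:1):0.15):0.15):9.7,out1:11);"
)

# Six ingroup species with internal branches >=5 units: gene trees almost
# always display the species-tree clades.
_LOW_ILS_TREE = (
    "((((sp1:2,sp2:2):5,(sp3:2,sp4:2):5):5,(sp5:2,sp6:2):10):10,out1:22);"
)


def _preset(name: str) -> MSCModel:
    if name == "pine_full":
        samples = {f"sp{i+1}": 14 for i in range(8)}
        samples.update({f"out{k}": 3 for k in (1, 2, 3)})
        return MSCModel(read_newick(_PINE_TREE), samples, locus_count=121,
                        locus_length=390, scale=0.01, missingness=0.15)
    if name == "pine_small":
        samples = {f"sp{i+1}": 3 for i in range(8)}
        samples.update({f"out{k}": 1 for k in (1, 2, 3)})
        return MSCModel(read_newick(_PINE_TREE), samples, locus_count=20,
                        locus_length=200, scale=0.01, missingness=0.1)
    if name == "high_ils":
        samples = {f"sp{i+1}": 2 for i in range(8)}
        samples["out1"] = 1
        return MSCModel(read_newick(_HIGH_ILS_TREE), samples, locus_count=15,
                        locus_length=300, scale=0.01, missingness=0.0)
    if name == "low_ils":
        samples = {f"sp{i+1}": 2 for i in range(6)}
        samples["out1"] = 1
        return MSCModel(read_newick(_LOW_ILS_TREE), samples, locus_count=30,
                        locus_length=300, scale=0.004, missingness=0.0)
    raise ValueError(f"unknown preset {name!r}")


PRESETS = ("pine_full", "pine_small", "high_ils", "low_ils")


def generate_pine_like_dataset(
    preset: str, seed: int, **overrides
) -> Tuple[MultilocusDataset, SimulatedTruth]:
    """Generate a full multilocus dataset plus its simulated truth.

    ``overrides`` may replace any :class:`MSCModel` field of the preset
    (e.g. ``locus_count=30`` for a reduced run).
    """
    model = _preset(preset)
    for key, val in overrides.items():
        if not hasattr(model, key):
            raise TypeError(f"unknown model field {key!r}")
        setattr(model, key, val)
    rng = np.random.default_rng(seed)
    ingroup = sorted(
        (l.taxon.label for l in model.species_tree.leaf_node_iter()
         if not l.taxon.label.startswith("out")),
        key=lambda s: (len(s), s),
    )
    outgroups = sorted(
        l.taxon.label for l in model.species_tree.leaf_node_iter()
        if l.taxon.label.startswith("out")
    )
    species = ingroup + outgroups
    species_map = {
        f"{sp}_{i + 1}": sp
        for sp in species
        for i in range(model.samples_per_species.get(sp, 1))
    }
    if model.rate_sigma > 0:
        rates = rng.lognormal(0.0, model.rate_sigma, size=model.locus_count)
    else:
        rates = np.ones(model.locus_count)

    gene_trees: List[dendropy.Tree] = []
    loci: List[LocusAlignment] = []
    for l in range(model.locus_count):
        gt = simulate_msc_gene_tree(model, rng)
        gene_trees.append(gt)
        loci.append(
            simulate_alignment(gt, model, rng, locus_id=f"locus{l + 1:03d}",
                               rate_multiplier=float(rates[l]))
        )
    dataset = MultilocusDataset(loci, species_map, species, len(ingroup))
    dataset = apply_missingness(dataset, model.missingness, rng)
    # keep the truth consistent with the realized missingness pattern
    pruned_trees: List[dendropy.Tree] = []
    for gt, loc in zip(gene_trees, dataset.loci):
        present = {r.individual_id for r in loc.records}
        if present != {l.taxon.label for l in gt.leaf_node_iter()}:
            gt = gt.clone(depth=1)
            gt.retain_taxa_with_labels(sorted(present))
            gt.suppress_unifurcations()
            gt.is_rooted = True
        pruned_trees.append(gt)
    truth = SimulatedTruth(model.species_tree, pruned_trees, dataset.loci)
    return dataset, truth
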