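"""Strategy enumeration and the across-loci bootstrap engine.

A *strategy* is a (species-tree method, gene-tree method, outgroup) triple;
the full design crosses 6 species-tree methods x 4 gene-tree methods x 3
outgroups = 72 strategies.  Each strategy uses the derived dataset its method
pair calls for: concatenation-based methods use Ds (Dp for M), consensus
methods use the zero-distance-filtered Ds0 (Dp0 for M).

Per bootstrap replicate, whole loci are drawn with replacement (sites within
a locus are never resampled), gene trees are re-inferred from the resampled
loci, the species-tree method is applied, and the rooted ingroup topology is
recorded.  Clade counts across the B replicates feed the strategies x clades
matrix S.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import dendropy
import numpy as np

from . import genetrees, speciestree
from .datasets import DatasetRole
from .distances import (SpeciesDistanceMatrix, UndefinedDistanceError,
                        locus_pair_sums)
from .io import (GENE_TREE_METHODS, SPECIES_TREE_METHODS, LocusAlignment,
                 MultilocusDataset, SequenceRecord)
from .trees import clade_masks, leaf_labels, root_with_outgroup

log = logging.getLogger("treestrat")

__all__ = [
    "StrategyDescriptor",
    "enumerate_strategies",
    "bootstrap_resample",
    "run_strategy",
    "collect_clades",
    "CladeCountMatrix",
    "build_clade_matrix",
    "possible_nontrivial_clades",
]

_CONCAT_METHODS = ("concatenation", "smrt")
_CONSENSUS_METHODS = ("steac", "star", "rtc", "mdc")


def _role_for(species_tree_method: str, gene_tree_method: str) -> str:
    if species_tree_method in _CONCAT_METHODS:
        return "Dp" if gene_tree_method == "m" else "Ds"
    return "Dp0" if gene_tree_method == "m" else "Ds0"


@dataclass(frozen=True)
class StrategyDescriptor:
    species_tree_method: str
    gene_tree_method: str
    outgroup: str

    def __post_init__(self) -> None:
        if self.species_tree_method not in SPECIES_TREE_METHODS:
            raise ValueError(f"unknown species-tree method {self.species_tree_method!r}")
        if self.gene_tree_method not in GENE_TREE_METHODS:
            raise ValueError(f"unknown gene-tree method {self.gene_tree_method!r}")

    @property
    def dataset_role(self) -> str:
        return _role_for(self.species_tree_method, self.gene_tree_method)

    @property
    def label(self) -> str:
        return (f"{self.species_tree_method.upper()}+"
                f"{self.gene_tree_method.upper()}+{self.outgroup}")


def enumerate_strategies(
    species_tree_methods: Sequence[str] = SPECIES_TREE_METHODS,
    gene_tree_methods: Sequence[str] = GENE_TREE_METHODS,
    outgroups: Sequence[str] = (),
) -> List[StrategyDescriptor]:
    """Full cross product with the role mapping attached."""
    return [
        StrategyDescriptor(sm, gm, og)
        for sm, gm, og in itertools.product(
            species_tree_methods, gene_tree_methods, outgroups
        )
    ]


def bootstrap_resample(role: DatasetRole, rng: np.random.Generator) -> List[str]:
    """Draw L locus ids with replacement from a derived dataset."""
    ids = role.locus_ids
    if not ids:
        raise ValueError(f"role {role.label} has no loci")
    picks = rng.integers(len(ids), size=len(ids))
    return [ids[i] for i in picks]


class _StrategyRunner:
    """Precomputes per-locus inputs for one strategy and executes replicates."""

    def __init__(
        self,
        strategy: StrategyDescriptor,
        roles: Mapping[str, DatasetRole],
        puzzling_orders: int = 100,
        mdc_mode: str = "exact",
    ):
        self.strategy = strategy
        self.role = roles[strategy.dataset_role]
        self.dataset = self.role.dataset
        self.puzzling_orders = puzzling_orders
        self.mdc_mode = mdc_mode
        self.scope = list(self.dataset.ingroup) + [strategy.outgroup]
        if strategy.outgroup not in self.dataset.outgroups:
            raise ValueError(f"{strategy.outgroup!r} is not an outgroup species")
        self._sp_alignments: Dict[str, LocusAlignment] = {}
        self._tables: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}

    # -- per-locus inputs ---------------------------------------------------

    def species_alignment(self, locus_id: str) -> LocusAlignment:
        """Locus restricted to the selected individuals of the strategy scope,
        rows relabeled by species."""
        if locus_id not in self._sp_alignments:
            locus = next(l for l in self.role.loci if l.locus_id == locus_id)
            chosen = self.role.selection[locus_id]
            recs = []
            for sp in self.scope:
                rec = locus.record_for(chosen[sp])
                recs.append(SequenceRecord(sp, sp, locus_id, rec.residues))
            self._sp_alignments[locus_id] = LocusAlignment(locus_id, recs)
        return self._sp_alignments[locus_id]

    def pair_tables(self, locus_id: str) -> Tuple[np.ndarray, np.ndarray]:
        if locus_id not in self._tables:
            locus = next(l for l in self.role.loci if l.locus_id == locus_id)
            self._tables[locus_id] = locus_pair_sums(locus, self.dataset)
        return self._tables[locus_id]

    def _scoped_matrix(self, D: np.ndarray, N: np.ndarray, strict: bool
                       ) -> SpeciesDistanceMatrix:
        species = self.dataset.species
        idx = [species.index(s) for s in self.scope]
        Ds = D[np.ix_(idx, idx)]
        Ns = N[np.ix_(idx, idx)]
        off = ~np.eye(len(idx), dtype=bool)
        if (Ns[off] == 0).any():
            raise UndefinedDistanceError("zero overlap within strategy scope")
        vals = np.zeros_like(Ds, dtype=float)
        vals[off] = Ds[off] / Ns[off]
        return SpeciesDistanceMatrix(list(self.scope), vals, "pooled")

    def pooled_matrix(self, locus_ids: Sequence[str]) -> SpeciesDistanceMatrix:
        k = len(self.dataset.species)
        D = np.zeros((k, k), dtype=np.int64)
        N = np.zeros((k, k), dtype=np.int64)
        for lid in locus_ids:
            d, n = self.pair_tables(lid)
            D += d
            N += n
        return self._scoped_matrix(D, N, strict=True)

    def per_locus_matrix(self, locus_id: str) -> SpeciesDistanceMatrix:
        d, n = self.pair_tables(locus_id)
        return self._scoped_matrix(d, n, strict=True)

    def concatenated(self, locus_ids: Sequence[str]) -> LocusAlignment:
        parts: Dict[str, List[str]] = {sp: [] for sp in self.scope}
        for lid in locus_ids:
            aln = self.species_alignment(lid)
            for rec in aln.records:
                parts[rec.individual_id].append(rec.residues)
        recs = [
            SequenceRecord(sp, sp, "concatenated", "".join(parts[sp]))
            for sp in self.scope
        ]
        return LocusAlignment("concatenated", recs)

    # -- one replicate ------------------------------------------------------

    def estimate(self, locus_ids: Sequence[str], rng: np.random.Generator
                 ) -> dendropy.Tree:
        st = self.strategy
        method, gm, og = st.species_tree_method, st.gene_tree_method, st.outgroup
        ingroup = self.dataset.ingroup
        if method == "concatenation":
            if gm == "m":
                return speciestree.concatenation_estimate(
                    None, "m", og, rng, pooled_matrix=self.pooled_matrix(locus_ids)
                )
            return speciestree.concatenation_estimate(
                self.concatenated(locus_ids), gm, og, rng
            )
        if method == "smrt":
            if gm == "m":
                return speciestree.smrt_estimate(
                    None, "m", og, ingroup, rng,
                    pooled_matrix=self.pooled_matrix(locus_ids),
                )
            return speciestree.smrt_estimate(
                self.concatenated(locus_ids), gm, og, ingroup, rng
            )
        # consensus methods need per-locus gene trees
        gene_trees = []
        for lid in locus_ids:
            if gm == "m":
                tree = genetrees.neighbor_joining(self.per_locus_matrix(lid))
            else:
                tree = genetrees.infer_gene_tree(self.species_alignment(lid), gm, rng)
            gene_trees.append(tree)
        if method == "steac":
            return speciestree.steac_estimate(gene_trees, og)
        if method == "star":
            # STAR ranks need rooted gene trees; root each at the outgroup
            rooted = [root_with_outgroup(t, og, prune_outgroup=False)
                      for t in gene_trees]
            return speciestree.star_estimate(rooted, og)
        rooted = [root_with_outgroup(t, og, prune_outgroup=True)
                  for t in gene_trees]
        if method == "rtc":
            return speciestree.rtc_estimate(rooted, rng, self.puzzling_orders)
        if method == "mdc":
            return speciestree.mdc_estimate(rooted, rng, mode=self.mdc_mode)
        raise ValueError(f"unknown species-tree method {method!r}")


def run_strategy(
    strategy: StrategyDescriptor,
    roles: Mapping[str, DatasetRole],
    B: int,
    rng: np.random.Generator,
    puzzling_orders: int = 100,
    mdc_mode: str = "exact",
    max_attempts: int = 3,
) -> List[dendropy.Tree]:
    """B bootstrap species-tree estimates (rooted ingroup topologies).

    A replicate whose inference fails (e.g. an undefined distance after
    resampling) is re-drawn up to ``max_attempts`` times, keeping the number
    of loci per replicate fixed at L.
    """
    runner = _StrategyRunner(strategy, roles, puzzling_orders, mdc_mode)
    out: List[dendropy.Tree] = []
    for _ in range(B):
        for attempt in range(max_attempts):
            locus_ids = bootstrap_resample(runner.role, rng)
            try:
                out.append(runner.estimate(locus_ids, rng))
                break
            except UndefinedDistanceError as exc:
                log.warning("%s: replicate re-drawn (%s)", strategy.label, exc)
        else:
            raise RuntimeError(
                f"{strategy.label}: {max_attempts} replicate attempts failed"
            )
    return out


def collect_clades(trees: Sequence[dendropy.Tree]) -> Dict[int, int]:
    """Counts of non-trivial clades across trees (bitmasks over the sorted
    shared leaf set)."""
    if not trees:
        return {}
    labels = sorted(leaf_labels(trees[0]))
    counts: Dict[int, int] = {}
    for t in trees:
        if sorted(leaf_labels(t)) != labels:
            raise ValueError("trees do not share a leaf set")
        for m in clade_masks(t, labels):
            counts[m] = counts.get(m, 0) + 1
    return counts


def possible_nontrivial_clades(m: int) -> int:
    """Number of possible non-trivial clades on m taxa: sum C(m,k), 2<=k<=m-1."""
    return sum(math.comb(m, k) for k in range(2, m))


@dataclass
class CladeCountMatrix:
    """Strategies x observed-clades bootstrap count matrix S."""

    strategies: List[StrategyDescriptor]
    clades: List[int]  # bitmask columns over `labels`
    values: np.ndarray  # integers in [0, B]
    B: int
    labels: List[str]  # ingroup species order for the bitmasks

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.shape != (len(self.strategies), len(self.clades)):
            raise ValueError("matrix shape mismatch")
        if v.size and (v.min() < 0 or v.max() > self.B):
            raise ValueError("entries must lie in [0, B]")
        self.values = v.astype(np.int64)

    def row(self, strategy: StrategyDescriptor) -> np.ndarray:
        return self.values[self.strategies.index(strategy)]

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            cols = ["".join(str(m >> i & 1) for i in range(len(self.labels)))
                    for m in self.clades]
            fh.write("strategy\t" + "\t".join(cols) + "\n")
            for st, row in zip(self.strategies, self.values):
                fh.write(st.label + "\t" + "\t".join(map(str, row)) + "\n")


def build_clade_matrix(
    per_strategy: Sequence[Tuple[StrategyDescriptor, Mapping[int, int]]],
    B: int,
    labels: Sequence[str],
) -> CladeCountMatrix:
    """Assemble S from per-strategy clade counts (equal B per row); columns
    are the union of observed clades ordered by descending total count, then
    bitmask."""
    for st, counts in per_strategy:
        for c in counts.values():
            if c > B:
                raise ValueError(f"{st.label}: clade count exceeds B")
    totals: Dict[int, int] = {}
    for _, counts in per_strategy:
        for mask, c in counts.items():
            totals[mask] = totals.get(mask, 0) + c
    clades = sorted(totals, key=lambda m: (-totals[m], m))
    values = np.zeros((len(per_strategy), len(clades)), dtype=np.int64)
    col = {m: j for j, m in enumerate(clades)}
    for i, (_, counts) in enumerate(per_strategy):
        for mask, c in counts.items():
            values[i, col[mask]] = c
    return CladeCountMatrix(
        [st for st, _ in per_strategy], clades, values, B, list(labels)
    )
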