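"""Pairwise and species-level p-distances.

The species-level distance between species *i* and *j* is the weighted average
p-distance over cross-species individual pairs: summed differences divided by
summed overlap, either within one locus (the per-locus matrix ``P^l``) or
pooled across a locus multiset (the pooled matrix ``P^all``).  The pooled form
equals the p-distance computed on a concatenated alignment, which is why all
accumulation here is done on integer ``(d, n)`` pairs and divided exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .io import GAP_CHARS, LocusAlignment, MultilocusDataset, SequenceRecord

__all__ = [
    "PairOverlap",
    "pair_overlap",
    "p_distance",
    "SpeciesDistanceMatrix",
    "species_distance_pooled",
    "species_distance_per_locus",
    "single_individual_matrix",
    "locus_pair_sums",
    "UndefinedDistanceError",
]

_GAP = np.frombuffer(b"-?", dtype=np.uint8)


class UndefinedDistanceError(ValueError):
    """Zero overlap makes a p-distance undefined."""


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class PairOverlap:
    """Overlap ``n`` (columns where neither sequence is gap/missing) and the
    number of differing such columns ``d``."""

    n: int
    d: int

    def __post_init__(self) -> None:
        if not (0 <= self.d <= self.n):
            raise ValueError("requires 0 <= d <= n")


def _codes(residues: str) -> np.ndarray:
    return np.frombuffer(residues.encode("ascii"), dtype=np.uint8)


def pair_overlap(a: SequenceRecord, b: SequenceRecord) -> PairOverlap:
    """Count overlapping non-gap non-missing columns and differences."""
    if len(a.residues) != len(b.residues):
        raise AlignmentError("sequences have unequal lengths")
    ca, cb = _codes(a.residues), _codes(b.residues)
    valid = ~(np.isin(ca, _GAP) | np.isin(cb, _GAP))
    n = int(valid.sum())
    d = int((valid & (ca != cb)).sum())
    return PairOverlap(n, d)


def p_distance(a: SequenceRecord, b: SequenceRecord) -> float:
    ov = pair_overlap(a, b)
    if ov.n == 0:
        raise UndefinedDistanceError(
            f"zero overlap between {a.individual_id} and {b.individual_id}"
        )
    return ov.d / ov.n


@dataclass
class SpeciesDistanceMatrix:
    """Symmetric species-level p-distance matrix.

    ``undefined`` marks entries whose overlap sum was zero; such a matrix is
    rejected by neighbor-joining, which needs a complete matrix.
    """

    labels: List[str]
    values: np.ndarray
    provenance: str = "single_individual"  # per_locus | pooled | single_individual
    undefined: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("matrix is not symmetric")
        self.values = v
        if self.undefined is None:
            self.undefined = np.zeros(v.shape, dtype=bool)

    @property
    def complete(self) -> bool:
        return not self.undefined.any()

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(lab + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")


def locus_pair_sums(
    locus: LocusAlignment, dataset: MultilocusDataset
) -> Tuple[np.ndarray, np.ndarray]:
    """Species x species integer tables ``(D, N)`` of summed differences and
    overlaps over cross-species individual pairs at one locus.

    These tables are the sufficient statistics for both the per-locus and the
    pooled species matrices; bootstrap resampling just re-adds them.
    """
    sp = dataset.species
    idx = {s: i for i, s in enumerate(sp)}
    k = len(sp)
    D = np.zeros((k, k), dtype=np.int64)
    N = np.zeros((k, k), dtype=np.int64)
    recs = locus.records
    codes = [_codes(r.residues) for r in recs]
    gap = [np.isin(c, _GAP) for c in codes]
    for a in range(len(recs)):
        ia = idx[recs[a].species_id]
        for b in range(a + 1, len(recs)):
            ib = idx[recs[b].species_id]
            if ia == ib:
                continue
            valid = ~(gap[a] | gap[b])
            n = int(valid.sum())
            d = int((valid & (codes[a] != codes[b])).sum())
            D[ia, ib] += d
            D[ib, ia] += d
            N[ia, ib] += n
            N[ib, ia] += n
    return D, N


def _ratio_matrix(
    D: np.ndarray, N: np.ndarray, labels: Sequence[str], provenance: str,
    strict: bool,
) -> SpeciesDistanceMatrix:
    k = len(labels)
    off = ~np.eye(k, dtype=bool)
    undefined = off & (N == 0)
    if strict and undefined.any():
        i, j = np.argwhere(undefined)[0]
        raise UndefinedDistanceError(
            f"zero pooled overlap for species pair ({labels[i]}, {labels[j]})"
        )
    vals = np.zeros((k, k), dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(N > 0, D / np.maximum(N, 1), 0.0)
    vals[off] = ratio[off]
    return SpeciesDistanceMatrix(list(labels), vals, provenance, undefined)


def species_distance_pooled(
    loci: Iterable[LocusAlignment], dataset: MultilocusDataset,
    tables: Optional[Dict[str, Tuple[np.ndarray, np.ndarray]]] = None,
) -> SpeciesDistanceMatrix:
    """Pooled species matrix ``P^all`` over a locus multiset.

    A locus appearing twice in ``loci`` (bootstrap resampling) contributes its
    ``(d, n)`` sums twice.  ``tables`` optionally caches per-locus sums keyed
    by locus id.
    """
    k = len(dataset.species)
    D = np.zeros((k, k), dtype=np.int64)
    N = np.zeros((k, k), dtype=np.int64)
    for loc in loci:
        if tables is not None:
            if loc.locus_id not in tables:
                tables[loc.locus_id] = locus_pair_sums(loc, dataset)
            d, n = tables[loc.locus_id]
        else:
            d, n = locus_pair_sums(loc, dataset)
        D += d
        N += n
    return _ratio_matrix(D, N, dataset.species, "pooled", strict=True)


def species_distance_per_locus(
    locus: LocusAlignment, dataset: MultilocusDataset
) -> SpeciesDistanceMatrix:
    """Per-locus species matrix ``P^l``; zero-overlap pairs are flagged
    undefined rather than raised (the zero-distance filter inspects them)."""
    D, N = locus_pair_sums(locus, dataset)
    return _ratio_matrix(D, N, dataset.species, "per_locus", strict=False)


def single_individual_matrix(locus: LocusAlignment) -> SpeciesDistanceMatrix:
    """p-distance matrix between per-species records (one record per species)."""
    species = [r.species_id for r in locus.records]
    if len(species) != len(set(species)):
        raise ValueError("alignment has more than one record for a species")
    k = len(species)
    vals = np.zeros((k, k), dtype=float)
    for i in range(k):
        for j in range(i + 1, k):
            vals[i, j] = vals[j, i] = p_distance(locus.records[i], locus.records[j])
    return SpeciesDistanceMatrix(species, vals, "single_individual")
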