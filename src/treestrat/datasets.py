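"""Construction of the four derived datasets Ds, Ds0, Dp and Dp0.

Ds picks, per locus, one individual per species so that the summed pairwise
overlap ``n`` is maximal, breaking ties by maximal summed differences ``d`` and
then uniformly at random.  Ds0 keeps the Ds loci whose selected individuals
differ between every distinct species pair (outgroup-outgroup pairs exempt).
Dp is the full dataset; Dp0 keeps the loci whose per-locus species-level
p-distance is nonzero for every such pair.  The Ds0 locus set is always a
subset of the Dp0 locus set.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .distances import locus_pair_sums, pair_overlap
from .io import LocusAlignment, MultilocusDataset

log = logging.getLogger("treestrat")

__all__ = ["DatasetRole", "select_Ds", "filter_Ds0", "build_Dp", "filter_Dp0",
           "build_all_roles", "EXHAUSTIVE_LIMIT"]

#: largest per-locus choice-product searched exhaustively; larger loci use
#: greedy coordinate ascent with restarts
EXHAUSTIVE_LIMIT = 1_000_000


@dataclass
class DatasetRole:
    """A derived dataset: retained loci and (for the Ds family) the selected
    individual per species per locus."""

    label: str  # Ds | Ds0 | Dp | Dp0
    dataset: MultilocusDataset
    locus_ids: List[str]
    selection: Optional[Dict[str, Dict[str, str]]] = None  # locus -> species -> individual

    @property
    def loci(self) -> List[LocusAlignment]:
        keep = set(self.locus_ids)
        return [l for l in self.dataset.loci if l.locus_id in keep]

    def selected_alignment(self, locus: LocusAlignment) -> LocusAlignment:
        """Restrict a locus to the selected one-individual-per-species rows."""
        if self.selection is None:
            raise ValueError(f"role {self.label} carries no per-locus selection")
        chosen = self.selection[locus.locus_id]
        return locus.restrict(list(chosen.values()))

    def write_report(self, path: str) -> None:
        """Selection report TSV: locus, species, chosen individual, n, d."""
        if self.selection is None:
            raise ValueError("no selection to report")
        by_id = {l.locus_id: l for l in self.dataset.loci}
        with open(path, "w") as fh:
            fh.write("locus\tspecies\tindividual\tn\td\n")
            for lid in self.locus_ids:
                locus = by_id[lid]
                sub = self.selected_alignment(locus)
                n, d = _subset_score([r for r in sub.records])
                for sp, ind in sorted(self.selection[lid].items()):
                    fh.write(f"{lid}\t{sp}\t{ind}\t{n}\t{d}\n")


def _subset_score(records) -> Tuple[int, int]:
    n = d = 0
    for a, b in itertools.combinations(records, 2):
        ov = pair_overlap(a, b)
        n += ov.n
        d += ov.d
    return n, d


def _pair_tables(locus: LocusAlignment) -> Tuple[List[str], np.ndarray, np.ndarray]:
    """(individual ids, N, D) pairwise integer tables for one locus."""
    ids = [r.individual_id for r in locus.records]
    k = len(ids)
    N = np.zeros((k, k), dtype=np.int64)
    D = np.zeros((k, k), dtype=np.int64)
    for i, j in itertools.combinations(range(k), 2):
        ov = pair_overlap(locus.records[i], locus.records[j])
        N[i, j] = N[j, i] = ov.n
        D[i, j] = D[j, i] = ov.d
    return ids, N, D


def _score_choice(choice: Sequence[int], N: np.ndarray, D: np.ndarray) -> Tuple[int, int]:
    idx = np.asarray(choice)
    sub_n = N[np.ix_(idx, idx)]
    sub_d = D[np.ix_(idx, idx)]
    return int(sub_n.sum() // 2), int(sub_d.sum() // 2)


def _select_locus(
    locus: LocusAlignment,
    dataset: MultilocusDataset,
    rng: np.random.Generator,
) -> Dict[str, str]:
    """Choose one individual per species maximizing (n, d) lexicographically."""
    by_sp = dataset.individuals_by_species(locus)
    for sp in dataset.species:
        if not by_sp[sp]:
            raise ValueError(
                f"species {sp!r} has no data at locus {locus.locus_id!r}"
            )
    ids, N, D = _pair_tables(locus)
    pos = {ind: i for i, ind in enumerate(ids)}
    groups = [[pos[i] for i in by_sp[sp]] for sp in dataset.species]
    size = int(np.prod([len(g) for g in groups]))
    if size <= EXHAUSTIVE_LIMIT:
        best: List[Tuple[int, ...]] = []
        best_score = (-1, -1)
        for combo in itertools.product(*groups):
            score = _score_choice(combo, N, D)
            if score > best_score:
                best_score = score
                best = [combo]
            elif score == best_score:
                best.append(combo)
        chosen = best[rng.integers(len(best))] if len(best) > 1 else best[0]
    else:
        chosen = _greedy_select(groups, N, D, rng)
    return {sp: ids[c] for sp, c in zip(dataset.species, chosen)}


def _greedy_select(
    groups: List[List[int]], N: np.ndarray, D: np.ndarray,
    rng: np.random.Generator, restarts: int = 8, sweeps: int = 20,
) -> Tuple[int, ...]:
    """Coordinate-ascent on the (n, d) objective with random restarts."""
    best_choice = None
    best_score = (-1, -1)
    for _ in range(restarts):
        choice = [g[rng.integers(len(g))] for g in groups]
        for _ in range(sweeps):
            improved = False
            for gi, g in enumerate(groups):
                cur = _score_choice(choice, N, D)
                for cand in g:
                    if cand == choice[gi]:
                        continue
                    trial = list(choice)
                    trial[gi] = cand
                    sc = _score_choice(trial, N, D)
                    if sc > cur:
                        choice = trial
                        cur = sc
                        improved = True
            if not improved:
                break
        score = _score_choice(choice, N, D)
        if score > best_score:
            best_score = score
            best_choice = tuple(choice)
    return best_choice


def select_Ds(dataset: MultilocusDataset, rng: np.random.Generator) -> DatasetRole:
    """Per-locus optimal one-individual-per-species selection (dataset Ds)."""
    selection = {
        loc.locus_id: _select_locus(loc, dataset, rng) for loc in dataset.loci
    }
    return DatasetRole("Ds", dataset, [l.locus_id for l in dataset.loci], selection)


def _exempt(sp_a: str, sp_b: str, dataset: MultilocusDataset) -> bool:
    """Distinct outgroup-outgroup pairs are exempt from zero-distance filters."""
    outs = set(dataset.outgroups)
    return sp_a in outs and sp_b in outs


def filter_Ds0(ds: DatasetRole) -> DatasetRole:
    """Keep Ds loci with >=1 difference between every non-exempt species pair."""
    if ds.selection is None:
        raise ValueError("filter_Ds0 requires a Ds role with selections")
    dataset = ds.dataset
    keep: List[str] = []
    by_id = {l.locus_id: l for l in dataset.loci}
    for lid in ds.locus_ids:
        sub = ds.selected_alignment(by_id[lid])
        ok = True
        for a, b in itertools.combinations(sub.records, 2):
            if _exempt(a.species_id, b.species_id, dataset):
                continue
            if pair_overlap(a, b).d == 0:
                ok = False
                break
        if ok:
            keep.append(lid)
    return DatasetRole("Ds0", dataset, keep, ds.selection)


def build_Dp(dataset: MultilocusDataset) -> DatasetRole:
    """Dp is the starting dataset itself (all individuals, all loci)."""
    return DatasetRole("Dp", dataset, [l.locus_id for l in dataset.loci], None)


def filter_Dp0(dataset: MultilocusDataset) -> DatasetRole:
    """Keep loci whose per-locus species p-distance is nonzero for every
    non-exempt pair; loci with an undefined (zero-overlap) entry are dropped
    with a warning."""
    sp = dataset.species
    keep: List[str] = []
    for loc in dataset.loci:
        D, N = locus_pair_sums(loc, dataset)
        ok = True
        for i, j in itertools.combinations(range(len(sp)), 2):
            if _exempt(sp[i], sp[j], dataset):
                continue
            if N[i, j] == 0:
                log.warning(
                    "locus %s: undefined distance for pair (%s, %s); dropped",
                    loc.locus_id, sp[i], sp[j],
                )
                ok = False
                break
            if D[i, j] == 0:
                ok = False
                break
        if ok:
            keep.append(loc.locus_id)
    return DatasetRole("Dp0", dataset, keep, None)


def build_all_roles(
    dataset: MultilocusDataset, rng: np.random.Generator
) -> Dict[str, DatasetRole]:
    """Build the full role family {Ds, Ds0, Dp, Dp0} for a dataset."""
    ds = select_Ds(dataset, rng)
    return {
        "Ds": ds,
        "Ds0": filter_Ds0(ds),
        "Dp": build_Dp(dataset),
        "Dp0": filter_Dp0(dataset),
    }
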