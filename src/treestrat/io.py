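"""Readers/writers and run configuration.

File conventions
----------------
* one aligned FASTA file per locus; the locus id is the file stem;
* taxon map: 3-column TSV ``individual_id  species_id  role`` with role in
  ``{ingroup, outgroup}``;
* trees: Newick, one per line for tree sets;
* run configuration: YAML.

The alphabet is ``A C G T - ?`` where ``-`` is an alignment gap and ``?``
missing data; both are excluded identically from overlap counts downstream.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

log = logging.getLogger("treestrat")

ALPHABET = frozenset("ACGT-?")

GAP_CHARS = frozenset("-?")


class FormatError(ValueError):
    """Malformed input file (ragged alignment, bad symbol...)."""


class MappingError(KeyError):
    """Individual missing from the taxon map."""


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned sequence of one individual at one locus."""

    individual_id: str
    species_id: str
    locus_id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.individual_id or not self.species_id or not self.locus_id:
            raise FormatError("empty identifier in sequence record")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise FormatError(
                f"illegal symbols {sorted(bad)} in sequence for "
                f"{self.individual_id}@{self.locus_id}"
            )


@dataclass
class LocusAlignment:
    """Aligned sequences at one locus (>=2 records, equal lengths)."""

    locus_id: str
    records: List[SequenceRecord]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise FormatError(f"locus {self.locus_id}: needs >=2 sequences")
        lens = {len(r.residues) for r in self.records}
        if len(lens) != 1:
            raise FormatError(f"locus {self.locus_id}: ragged alignment {sorted(lens)}")
        inds = [r.individual_id for r in self.records]
        if len(inds) != len(set(inds)):
            raise FormatError(f"locus {self.locus_id}: duplicate individual")

    @property
    def length(self) -> int:
        return len(self.records[0].residues)

    def record_for(self, individual_id: str) -> Optional[SequenceRecord]:
        for r in self.records:
            if r.individual_id == individual_id:
                return r
        return None

    def restrict(self, individual_ids: Sequence[str]) -> "LocusAlignment":
        keep = set(individual_ids)
        recs = [r for r in self.records if r.individual_id in keep]
        return LocusAlignment(self.locus_id, recs)


@dataclass
class MultilocusDataset:
    """Ordered loci plus the individual->species map and species roles.

    ``species`` lists the ingroup species first (indices ``0..n_ingroup-1``)
    followed by the outgroups.
    """

    loci: List[LocusAlignment]
    species_map: Dict[str, str]
    species: List[str]
    n_ingroup: int

    def __post_init__(self) -> None:
        if not self.loci:
            raise FormatError("dataset has no loci")
        known = set(self.species_map)
        for loc in self.loci:
            for r in loc.records:
                if r.individual_id not in known:
                    raise MappingError(
                        f"individual {r.individual_id!r} absent from taxon map"
                    )
        if not (1 <= self.n_ingroup <= len(self.species)):
            raise FormatError("invalid ingroup count")

    @property
    def ingroup(self) -> List[str]:
        return self.species[: self.n_ingroup]

    @property
    def outgroups(self) -> List[str]:
        return self.species[self.n_ingroup:]

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def individuals_by_species(self, locus: LocusAlignment) -> Dict[str, List[str]]:
        out: Dict[str, List[str]] = {s: [] for s in self.species}
        for r in locus.records:
            out[r.species_id].append(r.individual_id)
        return out


def read_taxon_map(path: str) -> Tuple[Dict[str, str], List[str], int]:
    """Read the 3-column TSV taxon map.

    Returns ``(individual->species, ordered species list, n_ingroup)``; the
    species order is first-appearance with ingroups before outgroups.
    """
    mapping: Dict[str, str] = {}
    roles: Dict[str, str] = {}
    order: List[str] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{ln}: expected 3 tab-separated columns")
            ind, sp, role = parts
            if role not in ("ingroup", "outgroup"):
                raise FormatError(f"{path}:{ln}: role must be ingroup|outgroup")
            if ind in mapping:
                raise FormatError(f"{path}:{ln}: duplicate individual {ind!r}")
            mapping[ind] = sp
            if sp in roles and roles[sp] != role:
                raise FormatError(f"{path}:{ln}: conflicting role for species {sp!r}")
            roles[sp] = role
            if sp not in order:
                order.append(sp)
    species = [s for s in order if roles[s] == "ingroup"] + [
        s for s in order if roles[s] == "outgroup"
    ]
    n_ingroup = sum(1 for s in species if roles[s] == "ingroup")
    return mapping, species, n_ingroup


def write_taxon_map(path: str, dataset: MultilocusDataset) -> None:
    with open(path, "w") as fh:
        for ind, sp in sorted(dataset.species_map.items()):
            role = "ingroup" if sp in dataset.ingroup else "outgroup"
            fh.write(f"{ind}\t{sp}\t{role}\n")


def read_locus_fasta(path: str, taxon_map: Mapping[str, str]) -> LocusAlignment:
    """Read one aligned per-locus FASTA; records carry species assignments."""
    locus_id = os.path.splitext(os.path.basename(path))[0]
    records: List[SequenceRecord] = []
    for rec in SeqIO.parse(path, "fasta"):
        ind = rec.id
        if ind not in taxon_map:
            raise MappingError(f"individual {ind!r} absent from taxon map")
        records.append(
            SequenceRecord(ind, taxon_map[ind], locus_id, str(rec.seq).upper())
        )
    if not records:
        raise FormatError(f"{path}: no sequences")
    return LocusAlignment(locus_id, records)


def write_locus_fasta(path: str, locus: LocusAlignment) -> None:
    recs = [
        _BioRecord(Seq(r.residues), id=r.individual_id, description="")
        for r in locus.records
    ]
    SeqIO.write(recs, path, "fasta")


def read_dataset(fasta_dir: str, taxon_map_path: str) -> MultilocusDataset:
    """Read all ``*.fasta`` files of a directory as one multilocus dataset."""
    mapping, species, n_ingroup = read_taxon_map(taxon_map_path)
    paths = sorted(
        os.path.join(fasta_dir, p)
        for p in os.listdir(fasta_dir)
        if p.endswith((".fasta", ".fa"))
    )
    loci = [read_locus_fasta(p, mapping) for p in paths]
    return MultilocusDataset(loci, mapping, species, n_ingroup)


def write_dataset(out_dir: str, dataset: MultilocusDataset) -> None:
    os.makedirs(out_dir, exist_ok=True)
    for loc in dataset.loci:
        write_locus_fasta(os.path.join(out_dir, f"{loc.locus_id}.fasta"), loc)
    write_taxon_map(os.path.join(out_dir, "taxon_map.tsv"), dataset)


# ---------------------------------------------------------------------------
# run configuration

SPECIES_TREE_METHODS = ("concatenation", "smrt", "steac", "star", "rtc", "mdc")
GENE_TREE_METHODS = ("ml", "mp", "nj", "m")


@dataclass
class RunConfig:
    """Effective configuration of a pipeline run.

    ``bootstrap_count`` defaults to the study convention of 1000 replicates
    across loci.  All downstream randomness derives from ``seed``.
    """

    seed: int = 0
    bootstrap_count: int = 1000
    species_tree_methods: Tuple[str, ...] = SPECIES_TREE_METHODS
    gene_tree_methods: Tuple[str, ...] = GENE_TREE_METHODS
    outgroups: Tuple[str, ...] = ()
    puzzling_orders: int = 100
    kmeans_restarts: int = 10_000
    mdc_search: str = "exact"  # exact | heuristic
    rf_pair_budget: int = 1_000_000
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.bootstrap_count < 1:
            raise ConfigError("bootstrap_count must be >= 1")
        for m in self.species_tree_methods:
            if m not in SPECIES_TREE_METHODS:
                raise ConfigError(f"unknown species-tree method {m!r}")
        for m in self.gene_tree_methods:
            if m not in GENE_TREE_METHODS:
                raise ConfigError(f"unknown gene-tree method {m!r}")
        if self.mdc_search not in ("exact", "heuristic"):
            raise ConfigError(f"unknown MDC search mode {self.mdc_search!r}")


def load_run_config(path: str) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
    for key in ("species_tree_methods", "gene_tree_methods", "outgroups"):
        if key in raw:
            raw[key] = tuple(raw[key])
    cfg = RunConfig(**raw)
    log.info("effective config: %s", dataclasses.asdict(cfg))
    return cfg
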