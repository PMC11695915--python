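"""MAG classification against a loaded storage-matrix reference.

A bin is shredded into q-minimizers exactly like a reference genome; every
occurrence looks up its slot, non-sentinel hits are tallied into a resume
table (taxid -> occurrences, distinct hashes, rank), and a prevalence rule
picks genus, then species, then strain:

  genus   = argmax over summed occurrences (strain hits roll up to genus)
  species = argmax over summed strain occurrences within the genus
  strain  = argmax over ass2ref within the species, where
            ass2ref = distinct observed strain minimizers / ref_count(strain)

Below the ass2ref threshold (suggested 0.2) species/strain are dropped and
the call is genus-only.  All argmax ties break to the smaller taxid so a
run is deterministic.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .minimizers import KmerConfig, MinimizerProfile, profile_fasta
from .reference import BLACK, EMPTY, RefCatalog, StorageMatrix, address_of
from .taxonomy import TaxonomyTree

__all__ = [
    "TaxEntry",
    "ResumeTable",
    "Assignment",
    "DEFAULT_ASS2REF_THRESHOLD",
    "query_profile",
    "query_bin",
    "ass2ref",
    "assign_taxonomy",
    "classify_directory",
    "CSV_FIELDS",
]

logger = logging.getLogger("minitax")

DEFAULT_ASS2REF_THRESHOLD = 0.2

CSV_FIELDS = [
    "bin_name",
    "ass2ref",
    "taxid",
    "species_taxid",
    "genus_taxid",
    "family_taxid",
    "order_taxid",
    "class_taxid",
    "phylum_taxid",
    "superkingdom_taxid",
    "organism_name",
]


@dataclass
class TaxEntry:
    occurrences: int
    distinct: int
    rank: str  # "strain" | "genus"


@dataclass
class ResumeTable:
    """Per-bin tally of taxids hit by q-minimizers."""

    entries: dict[int, TaxEntry] = field(default_factory=dict)

    def __bool__(self) -> bool:
        return bool(self.entries)


@dataclass
class Assignment:
    bin_name: str
    ass2ref: float
    taxid: int
    rank: str  # "strain" | "genus"
    strain_taxid: Optional[int]
    species_taxid: Optional[int]
    genus_taxid: int
    lineage: dict[str, Optional[int]]
    organism_name: str
    capped: bool = False  # ass2ref hit the [0, 1] cap (hash-collision inflation)

    def csv_row(self) -> dict[str, str]:
        def fmt(t: Optional[int]) -> str:
            return "" if t is None else str(t)

        return {
            "bin_name": self.bin_name,
            "ass2ref": f"{self.ass2ref:.4f}",
            "taxid": str(self.taxid),
            "species_taxid": fmt(self.species_taxid),
            "genus_taxid": fmt(self.genus_taxid),
            "family_taxid": fmt(self.lineage.get("family")),
            "order_taxid": fmt(self.lineage.get("order")),
            "class_taxid": fmt(self.lineage.get("class")),
            "phylum_taxid": fmt(self.lineage.get("phylum")),
            "superkingdom_taxid": fmt(self.lineage.get("superkingdom")),
            "organism_name": self.organism_name,
        }


def query_profile(
    profile: MinimizerProfile, matrix: StorageMatrix, catalog: RefCatalog
) -> ResumeTable:
    """Look up every q-minimizer of a profile in the storage matrix."""
    table = ResumeTable()
    if profile.n_distinct == 0:
        return table
    # fold hashes onto slot addresses first: the matrix cannot distinguish
    # two hashes sharing a slot, so "distinct" counts distinct slots
    raw_addrs = address_of(profile.distinct, matrix.hash_bits)
    addrs, addr_inv = np.unique(raw_addrs, return_inverse=True)
    occ_per_addr = np.zeros(addrs.size, dtype=np.int64)
    np.add.at(occ_per_addr, addr_inv, profile.counts)
    values = matrix.slots[addrs]
    hit = (values != EMPTY) & (values != BLACK)
    if not hit.any():
        return table
    vals = values[hit].astype(np.int64)
    occ = occ_per_addr[hit]
    uniq, inv = np.unique(vals, return_inverse=True)
    occurrences = np.zeros(uniq.size, dtype=np.int64)
    distinct = np.zeros(uniq.size, dtype=np.int64)
    np.add.at(occurrences, inv, occ)
    np.add.at(distinct, inv, 1)
    for taxid, o, d in zip(uniq.tolist(), occurrences.tolist(), distinct.tolist()):
        rank = "strain" if taxid in catalog.strains else "genus"
        table.entries[taxid] = TaxEntry(occurrences=int(o), distinct=int(d), rank=rank)
    return table


def query_bin(
    fasta: str | Path,
    matrix: StorageMatrix,
    catalog: RefCatalog,
    config: Optional[KmerConfig] = None,
) -> ResumeTable:
    """Shred a MAG FASTA into q-minimizers and query the matrix.

    `config` defaults to the reference's own (k, n, h); a mismatching
    config is an error — the bin must be shredded exactly like the
    reference genomes were.
    """
    if config is None:
        config = catalog.config
    elif config != catalog.config:
        raise ValueError(
            f"config mismatch: reference built with {catalog.config}, got {config}"
        )
    return query_profile(profile_fasta(fasta, config), matrix, catalog)


def ass2ref(strain: int, table: ResumeTable, catalog: RefCatalog) -> float:
    """Distinct q-minimizers observed for a strain over its reference count.

    ref_count 0 guards to 0; hash-collision inflation is capped at 1.
    """
    if strain not in catalog.strains:
        raise KeyError(f"unknown strain taxid {strain}")
    denom = catalog.ref_count(strain)
    if denom == 0:
        return 0.0
    entry = table.entries.get(strain)
    numer = entry.distinct if entry is not None else 0
    return min(numer / denom, 1.0)


def assign_taxonomy(
    table: ResumeTable,
    catalog: RefCatalog,
    tree: Optional[TaxonomyTree] = None,
    threshold: float = DEFAULT_ASS2REF_THRESHOLD,
    bin_name: str = "",
) -> Optional[Assignment]:
    """Prevalence-based genus -> species -> strain call; None if the table
    is empty (unclassified bin)."""
    if not table:
        return None

    # genus prevalence: genus-rank occurrences plus rolled-up strain hits
    genus_score: dict[int, int] = {}
    for taxid, entry in table.entries.items():
        g = catalog.genus_of(taxid) if entry.rank == "strain" else taxid
        genus_score[g] = genus_score.get(g, 0) + entry.occurrences
    genus = min(g for g, s in genus_score.items() if s == max(genus_score.values()))

    # species prevalence among strains of the winning genus
    species_score: dict[int, int] = {}
    for taxid, entry in table.entries.items():
        if entry.rank != "strain" or catalog.genus_of(taxid) != genus:
            continue
        sp = catalog.strains[taxid].species_taxid
        if sp is None:
            continue
        species_score[sp] = species_score.get(sp, 0) + entry.occurrences

    species: Optional[int] = None
    strain: Optional[int] = None
    best_a2r = 0.0
    capped = False
    if species_score:
        species = min(
            sp for sp, s in species_score.items() if s == max(species_score.values())
        )
        candidates = [
            t
            for t, entry in table.entries.items()
            if entry.rank == "strain"
            and catalog.strains[t].species_taxid == species
        ]
        scored = [(ass2ref(t, table, catalog), t) for t in candidates]
        best_a2r = max(a for a, _ in scored)
        strain = min(t for a, t in scored if a == best_a2r)
        entry = table.entries[strain]
        capped = entry.distinct > catalog.ref_count(strain)

    if strain is None or best_a2r < threshold:
        # genus-only call ("retain those at the genus level")
        taxid, rank = genus, "genus"
        species_out = strain_out = None
    else:
        taxid, rank = strain, "strain"
        species_out, strain_out = species, strain

    if tree is not None and taxid in tree:
        lineage = tree.lineage8(taxid).as_dict()
        name = tree.name(taxid)
    else:
        lineage = dict(catalog.genera.get(genus, {}))
        name = ""
    return Assignment(
        bin_name=bin_name,
        ass2ref=best_a2r,
        taxid=taxid,
        rank=rank,
        strain_taxid=strain_out,
        species_taxid=species_out,
        genus_taxid=genus,
        lineage=lineage,
        organism_name=name,
        capped=capped,
    )


def classify_directory(
    bins_dir: str | Path,
    matrix: StorageMatrix,
    catalog: RefCatalog,
    tree: Optional[TaxonomyTree] = None,
    threshold: float = DEFAULT_ASS2REF_THRESHOLD,
    out_csv: Optional[str | Path] = None,
) -> list[Assignment]:
    """Classify every FASTA(.gz) bin in a directory; write the 11-field CSV.

    Rows are ordered by bin name; unclassified bins are logged and omitted
    from the CSV.  Unreadable files warn and the run continues.
    """
    bins_dir = Path(bins_dir)
    paths = sorted(
        p
        for p in bins_dir.iterdir()
        if p.suffix.lower() in {".fa", ".fasta", ".fna"}
        or p.name.lower().endswith((".fa.gz", ".fasta.gz", ".fna.gz"))
    )
    if not paths:
        raise ValueError(f"no FASTA bins found in {bins_dir}")

    assignments: list[Assignment] = []
    n_capped = 0
    for path in paths:
        bin_name = path.name
        for ext in (".gz", ".fa", ".fasta", ".fna"):
            if bin_name.endswith(ext):
                bin_name = bin_name[: -len(ext)]
        try:
            table = query_bin(path, matrix, catalog)
        except Exception as exc:  # unreadable bin: warn, continue
            logger.warning("skipping %s: %s", path.name, exc)
            continue
        assignment = assign_taxonomy(
            table, catalog, tree, threshold=threshold, bin_name=bin_name
        )
        if assignment is None:
            logger.info("unclassified bin %s: no reference minimizer hits", bin_name)
            continue
        if assignment.capped:
            n_capped += 1
        logger.info(
            "bin %s -> taxid %d (%s, ass2ref %.4f)",
            bin_name,
            assignment.taxid,
            assignment.rank,
            assignment.ass2ref,
        )
        assignments.append(assignment)
    if n_capped:
        logger.info("ass2ref capped at 1.0 for %d bin(s)", n_capped)

    if out_csv is not None:
        with open(out_csv, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=CSV_FIELDS)
            writer.writeheader()
            for assignment in assignments:
                writer.writerow(assignment.csv_row())
    return assignments
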