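"""Synthetic clades: genomes, taxonomy dumps, assembly summaries, MAG bins.

A clade is grown by substitution-only evolution: one root genome, genus
ancestors mutated from it at the between-genus rate, species ancestors from
each genus at the between-species rate, strain genomes from each species at
the within-strain rate.  With no indels, expected ANI between a genome and
its rate-r mutant is (1 - r) * 100, so sketching accuracy has a closed-form
target.  Emitted files mimic the real inputs: per-genome FASTA, NCBI-style
nodes/names dumps, a tab-delimited assembly summary, and a truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "FixtureSpec",
    "FixtureClade",
    "simulate_genome",
    "mutate",
    "make_clade",
    "shred_to_bin",
    "write_fasta",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class FixtureSpec:
    """Shape and divergence structure of a synthetic clade."""

    n_genera: int = 3
    species_per_genus: int = 2
    strains_per_species: int = 2
    genome_length: int = 50_000
    between_genus_div: float = 0.10
    between_species_div: float = 0.03
    within_strain_div: float = 0.005
    gc_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genera", "species_per_genus", "strains_per_species"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (
            0 <= self.within_strain_div
            < self.between_species_div
            < self.between_genus_div
            <= 0.3
        ):
            raise ValueError(
                "divergence rates must satisfy "
                "0 <= within_strain < between_species < between_genus <= 0.3"
            )


@dataclass
class GenomeRecord:
    accession: str
    strain_taxid: int
    species_taxid: int
    genus_taxid: int
    sequence: str


@dataclass
class FixtureClade:
    """In-memory clade plus (optionally) its on-disk rendering."""

    spec: FixtureSpec
    genomes: list[GenomeRecord]
    root_taxid: int = 1
    superkingdom_taxid: int = 2
    out_dir: Optional[Path] = None
    nodes_dump: Optional[Path] = None
    names_dump: Optional[Path] = None
    assembly_summary: Optional[Path] = None
    truth_table: Optional[Path] = None
    fasta_dir: Optional[Path] = None

    @property
    def truth(self) -> dict[str, dict[str, int]]:
        return {
            g.accession: {
                "strain": g.strain_taxid,
                "species": g.species_taxid,
                "genus": g.genus_taxid,
            }
            for g in self.genomes
        }

    def genus_taxids(self) -> list[int]:
        return sorted({g.genus_taxid for g in self.genomes})

    def species_taxids(self) -> list[int]:
        return sorted({g.species_taxid for g in self.genomes})

    def strain_taxids(self) -> list[int]:
        return sorted({g.strain_taxid for g in self.genomes})


def simulate_genome(
    length: int, gc_fraction: float = 0.5, seed: int | np.random.Generator = 0
) -> str:
    """I.i.d. random genome with the requested GC fraction."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not (0.0 <= gc_fraction <= 1.0):
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_at = (1.0 - gc_fraction) / 2.0
    p_gc = gc_fraction / 2.0
    codes = rng.choice(4, size=length, p=[p_at, p_gc, p_gc, p_at])
    return _BASES[codes].tobytes().decode("ascii")


def mutate(seq: str, rate: float, seed: int | np.random.Generator = 0) -> str:
    """Substitute each position, independently with probability `rate`, to a
    uniformly chosen *different* base."""
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    idx = lut[codes]
    hit = rng.random(codes.size) < rate
    shift = rng.integers(1, 4, size=codes.size)
    idx = np.where(hit, (idx + shift) % 4, idx)
    return _BASES[idx].tobytes().decode("ascii")


def write_fasta(path: Path, records: list[tuple[str, str]], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _dump_row(*fields: object) -> str:
    return "\t|\t".join(str(f) for f in fields) + "\t|\n"


def make_clade(
    spec: FixtureSpec,
    out_dir: Optional[str | Path] = None,
    strain_labels: bool = True,
) -> FixtureClade:
    """Grow a clade per the spec; optionally render it as files.

    With `strain_labels=False` the assembly summary's taxid column repeats
    the species taxid (no sub-species label), exercising strain refinement
    downstream; the taxonomy dumps then also omit the strain nodes.
    """
    rng = np.random.default_rng(spec.seed)
    root = simulate_genome(spec.genome_length, spec.gc_fraction, rng)
    genomes: list[GenomeRecord] = []
    for gi in range(spec.n_genera):
        genus_taxid = 100 + gi
        genus_seq = mutate(root, spec.between_genus_div, rng)
        for si in range(spec.species_per_genus):
            species_taxid = 1000 + gi * spec.species_per_genus + si
            species_seq = mutate(genus_seq, spec.between_species_div, rng)
            for ti in range(spec.strains_per_species):
                strain_taxid = 10000 + (
                    (gi * spec.species_per_genus + si) * spec.strains_per_species + ti
                )
                strain_seq = mutate(species_seq, spec.within_strain_div, rng)
                acc = f"SYN_{genus_taxid}_{species_taxid}_{strain_taxid}"
                genomes.append(
                    GenomeRecord(acc, strain_taxid, species_taxid, genus_taxid, strain_seq)
                )

    clade = FixtureClade(spec=spec, genomes=genomes)
    if out_dir is None:
        return clade

    out_dir = Path(out_dir)
    fasta_dir = out_dir / "genomes"
    fasta_dir.mkdir(parents=True, exist_ok=True)
    clade.out_dir, clade.fasta_dir = out_dir, fasta_dir

    for g in genomes:
        write_fasta(fasta_dir / f"{g.accession}.fa", [(g.accession, g.sequence)])

    nodes_path = out_dir / "nodes.dmp"
    names_path = out_dir / "names.dmp"
    with open(nodes_path, "w") as nodes_fh, open(names_path, "w") as names_fh:
        def emit(taxid: int, parent: int, rank: str, name: str) -> None:
            nodes_fh.write(_dump_row(taxid, parent, rank))
            names_fh.write(_dump_row(taxid, name, "", "scientific name"))

        emit(1, 1, "no rank", "root")
        emit(2, 1, "superkingdom", "Synthetica")
        for genus in clade.genus_taxids():
            emit(genus, 2, "genus", f"Genus{genus}")
        for species in clade.species_taxids():
            genus = next(g.genus_taxid for g in genomes if g.species_taxid == species)
            emit(species, genus, "species", f"Species {species}")
        if strain_labels:
            for strain in clade.strain_taxids():
                species = next(
                    g.species_taxid for g in genomes if g.strain_taxid == strain
                )
                emit(strain, species, "strain", f"Strain {strain}")
    clade.nodes_dump, clade.names_dump = nodes_path, names_path

    summary_path = out_dir / "assembly_summary.tsv"
    with open(summary_path, "w") as fh:
        fh.write("# assembly_accession\ttaxid\tspecies_taxid\tlocal_path\n")
        for g in genomes:
            taxid = g.strain_taxid if strain_labels else g.species_taxid
            fh.write(
                f"{g.accession}\t{taxid}\t{g.species_taxid}\t"
                f"{fasta_dir / (g.accession + '.fa')}\n"
            )
    clade.assembly_summary = summary_path

    truth_path = out_dir / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("bin\tstrain_taxid\tspecies_taxid\tgenus_taxid\n")
        for g in genomes:
            fh.write(
                f"{g.accession}\t{g.strain_taxid}\t{g.species_taxid}\t{g.genus_taxid}\n"
            )
    clade.truth_table = truth_path
    return clade


def shred_to_bin(
    genome: str,
    n_contigs: int,
    min_len: int = 500,
    seed: int | np.random.Generator = 0,
) -> list[tuple[str, str]]:
    """Cut a genome into contiguous non-overlapping contigs (a synthetic MAG).

    Breakpoints are random but every contig is >= min_len and total
    coverage is >= 90% of the genome (here: 100%, junction loss only
    affects minimizer windows, not bases).
    """
    length = len(genome)
    if n_contigs < 1:
        raise ValueError("n_contigs must be >= 1")
    if n_contigs * min_len > length:
        raise ValueError(
            f"cannot cut {length} nt into {n_contigs} contigs of >= {min_len} nt"
        )
    if n_contigs == 1:
        return [("contig_1", genome)]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # choose cut points leaving >= min_len between consecutive boundaries
    free = length - n_contigs * min_len
    extras = rng.multinomial(free, np.ones(n_contigs) / n_contigs)
    sizes = extras + min_len
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    return [
        (f"contig_{i + 1}", genome[bounds[i] : bounds[i + 1]])
        for i in range(n_contigs)
    ]
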