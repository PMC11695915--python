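"""Storage-matrix reference: build, serialize, load.

The reference is a flat array of 2**h unsigned 32-bit slots addressed by
minimizer hash (h = 32 covers the full hash space; the array is viewable
as 2**h / 8 rows by 8 columns).  Each slot is in one of four states:

    EMPTY (0)          minimizer never seen in any reference genome
    BLACK (2**32 - 1)  redundant: seen in more than one genus (absorbing)
    strain taxid       seen in exactly one strain
    genus taxid        seen in several strains of exactly one genus

One representative genome per strain (distinct-minimizer count nearest the
strain's median) feeds the fill algorithm, so the final matrix depends only
on the set of (strain, genus) pairs hitting each slot — never on insertion
order.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .minimizers import KmerConfig, MinimizerProfile
from .taxonomy import Lineage8, TaxonomyTree, operative_genus

__all__ = [
    "EMPTY",
    "BLACK",
    "StorageMatrix",
    "StrainInfo",
    "RefCatalog",
    "ReferenceFormatError",
    "select_representative",
    "slot_coords",
    "address_of",
    "matrix_footprint",
    "update_slot",
    "build_reference",
    "serialize_reference",
    "load_reference",
    "build_reference_from_files",
]

EMPTY = 0
BLACK = 2**32 - 1

_MAGIC = b"MTAXREF1"
_VERSION = 1


class ReferenceFormatError(ValueError):
    """Unreadable or corrupt serialized reference."""


@dataclass
class StorageMatrix:
    hash_bits: int
    slots: np.ndarray  # uint32, length 2**hash_bits

    @classmethod
    def zeros(cls, hash_bits: int) -> "StorageMatrix":
        if not (1 <= hash_bits <= 32):
            raise ValueError(f"hash_bits must be in [1, 32], got {hash_bits}")
        return cls(hash_bits, np.zeros(2**hash_bits, dtype=np.uint32))

    @property
    def n_slots(self) -> int:
        return 2**self.hash_bits

    def state_counts(self, catalog: "RefCatalog") -> dict[str, int]:
        """Slot tally by state: empty, black, strain-held, genus-held."""
        values, counts = np.unique(self.slots, return_counts=True)
        tally = {"empty": 0, "black": 0, "strain": 0, "genus": 0}
        for v, c in zip(values.tolist(), counts.tolist()):
            if v == EMPTY:
                tally["empty"] += c
            elif v == BLACK:
                tally["black"] += c
            elif v in catalog.strains:
                tally["strain"] += c
            else:
                tally["genus"] += c
        return tally


@dataclass
class StrainInfo:
    genus_taxid: int
    species_taxid: Optional[int]
    ref_count: int = 0


@dataclass
class RefCatalog:
    """Per-strain bookkeeping plus build metadata.

    ref_count(s) is the number of slots still held by strain s after all
    demotions/blacklisting — the ass2ref denominator.
    """

    config: KmerConfig
    strains: dict[int, StrainInfo] = field(default_factory=dict)
    genera: dict[int, dict[str, Optional[int]]] = field(default_factory=dict)
    n_genomes: int = 0

    def ref_count(self, strain_taxid: int) -> int:
        return self.strains[strain_taxid].ref_count

    def genus_of(self, strain_taxid: int) -> int:
        return self.strains[strain_taxid].genus_taxid

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RefCatalog):
            return NotImplemented
        return (
            self.config == other.config
            and self.strains == other.strains
            and self.genera == other.genera
            and self.n_genomes == other.n_genomes
        )


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def slot_coords(m: int, hash_bits: int = 32) -> tuple[int, int]:
    """(row, column) of a minimizer address: row = m // 8, column = m % 8."""
    if not (0 <= m < 2**hash_bits):
        raise ValueError(f"address {m} out of range for hash_bits={hash_bits}")
    return m // 8, m % 8


def address_of(m: int | np.ndarray, hash_bits: int = 32):
    """Slot address of a 32-bit minimizer hash: identity at h = 32,
    otherwise m mod 2**h (total, never fails for valid h)."""
    if hash_bits == 32:
        return m
    if isinstance(m, np.ndarray):
        return m & np.uint32(2**hash_bits - 1)
    return int(m) % 2**hash_bits


def matrix_footprint(hash_bits: int = 32) -> int:
    """Matrix weight in bytes: 4 bytes per slot times 2**h slots."""
    if not (1 <= hash_bits <= 32):
        raise ValueError(f"hash_bits must be in [1, 32], got {hash_bits}")
    return 4 * 2**hash_bits


# ---------------------------------------------------------------------------
# fill algorithm
# ---------------------------------------------------------------------------

def select_representative(
    genomes: Sequence[tuple[str, MinimizerProfile]]
) -> str:
    """Accession of the genome whose distinct-minimizer count is nearest the
    strain's median; ties break to the smaller count, then the
    lexicographically smallest accession."""
    if not genomes:
        raise ValueError("no genomes for representative selection")
    counts = [p.n_distinct for _, p in genomes]
    median = float(np.median(counts))
    best = min(
        zip(genomes, counts),
        key=lambda gc: (abs(gc[1] - median), gc[1], gc[0][0]),
    )
    return best[0][0]


def update_slot(
    current: int,
    strain: int,
    genus_of_strain: int,
    genus_of_current: Optional[int] = None,
) -> int:
    """One slot-state transition for a minimizer of `strain` (scalar contract).

    EMPTY -> strain; BLACK absorbs; the same strain or genus keeps the slot
    accessible; a *different* strain of the same genus demotes the slot to
    the shared genus taxid; a second genus blacks the slot.

    `genus_of_current` resolves the occupant when it is neither a sentinel
    nor `strain`/`genus_of_strain`; left None, any such occupant is treated
    as belonging to a different genus.
    """
    for taxid in (strain, genus_of_strain):
        if taxid in (EMPTY, BLACK):
            raise ValueError(f"taxid {taxid} collides with a sentinel")
    if current == EMPTY:
        return strain
    if current == BLACK:
        return BLACK
    if current == strain or current == genus_of_strain:
        return current
    if genus_of_current == genus_of_strain:
        return genus_of_strain
    return BLACK


def build_reference(
    strain_table: Mapping[int, Sequence[tuple[str, MinimizerProfile]]],
    tree: TaxonomyTree,
    config: KmerConfig,
) -> tuple[StorageMatrix, RefCatalog]:
    """Fill the storage matrix from one representative genome per strain.

    strain_table maps strain taxid -> [(accession, profile), ...].  Each
    strain's genus comes from its lineage, falling back to the operative
    genus (most specific family..superkingdom rank) when no genus rank
    exists; a strain resolving to nothing is an error naming its accessions.
    """
    catalog = RefCatalog(config=config)
    matrix = StorageMatrix.zeros(config.hash_bits)
    slots = matrix.slots

    # resolve genus per strain first so the value -> genus map is total
    genus_of_value: dict[int, int] = {}
    plan: list[tuple[int, int, MinimizerProfile]] = []
    for strain_taxid in sorted(strain_table):
        genomes = strain_table[strain_taxid]
        lineage = tree.lineage8(strain_taxid)
        genus = lineage.genus
        if genus is None:
            try:
                genus = operative_genus(lineage)
            except ValueError:
                accs = ", ".join(acc for acc, _ in genomes)
                raise ValueError(
                    f"strain {strain_taxid} ({accs}): no genus or operative genus"
                ) from None
        if strain_taxid in (EMPTY, BLACK) or genus in (EMPTY, BLACK):
            raise ValueError("taxid collides with a storage sentinel")
        rep = select_representative(genomes)
        profile = next(p for acc, p in genomes if acc == rep)
        genus_of_value[strain_taxid] = genus
        genus_of_value[genus] = genus
        catalog.strains[strain_taxid] = StrainInfo(
            genus_taxid=genus, species_taxid=lineage.species
        )
        if genus not in catalog.genera:
            glin = tree.lineage8(genus)
            catalog.genera[genus] = glin.as_dict()
        catalog.n_genomes += len(genomes)
        plan.append((strain_taxid, genus, profile))

    for strain_taxid, genus, profile in plan:
        if profile.n_distinct == 0:
            continue
        addrs = address_of(profile.distinct, config.hash_bits)
        cur = slots[addrs]
        uniq, inv = np.unique(cur, return_inverse=True)
        genus_of_cur = np.array(
            [genus_of_value.get(int(v), -1) for v in uniq], dtype=np.int64
        )[inv]
        new = np.where(
            cur == EMPTY,
            np.uint32(strain_taxid),
            np.where(
                cur == BLACK,
                np.uint32(BLACK),
                np.where(
                    cur == np.uint32(strain_taxid),
                    cur,
                    np.where(
                        genus_of_cur == genus,
                        np.uint32(genus),
                        np.uint32(BLACK),
                    ),
                ),
            ),
        ).astype(np.uint32)
        slots[addrs] = new

    # ref_count: slots still held by each strain
    values, counts = np.unique(slots, return_counts=True)
    held = dict(zip(values.tolist(), counts.tolist()))
    for strain_taxid, info in catalog.strains.items():
        info.ref_count = held.get(strain_taxid, 0)
    return matrix, catalog


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def serialize_reference(
    matrix: StorageMatrix, catalog: RefCatalog, path: str | Path
) -> None:
    """Write magic, version, (k, n, h), row-major LE slots, then a
    length-prefixed JSON catalogue block."""
    cat = {
        "k": catalog.config.k,
        "n": catalog.config.n,
        "hash_bits": catalog.config.hash_bits,
        "n_genomes": catalog.n_genomes,
        "strains": {
            str(t): {
                "genus_taxid": info.genus_taxid,
                "species_taxid": info.species_taxid,
                "ref_count": info.ref_count,
            }
            for t, info in catalog.strains.items()
        },
        "genera": {str(t): lin for t, lin in catalog.genera.items()},
    }
    blob = json.dumps(cat, sort_keys=True).encode("utf-8")
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<HBBB", _VERSION, catalog.config.k, catalog.config.n, matrix.hash_bits))
        fh.write(matrix.slots.astype("<u4").tobytes())
        fh.write(struct.pack("<Q", len(blob)))
        fh.write(blob)


def load_reference(path: str | Path) -> tuple[StorageMatrix, RefCatalog]:
    """Inverse of serialize_reference, bit-exact; refuses foreign or
    truncated files with distinct errors."""
    with open(path, "rb") as fh:
        magic = fh.read(8)
        if magic != _MAGIC:
            raise ReferenceFormatError(f"bad magic {magic!r}: not a reference file")
        head = fh.read(5)
        if len(head) < 5:
            raise ReferenceFormatError("truncated header")
        version, k, n, hash_bits = struct.unpack("<HBBB", head)
        if version != _VERSION:
            raise ReferenceFormatError(f"unsupported format version {version}")
        n_bytes = 4 * 2**hash_bits
        raw = fh.read(n_bytes)
        if len(raw) < n_bytes:
            raise ReferenceFormatError("truncated slot array")
        slots = np.frombuffer(raw, dtype="<u4").astype(np.uint32)
        len_raw = fh.read(8)
        if len(len_raw) < 8:
            raise ReferenceFormatError("truncated catalogue length")
        (blob_len,) = struct.unpack("<Q", len_raw)
        blob = fh.read(blob_len)
        if len(blob) < blob_len:
            raise ReferenceFormatError("truncated catalogue block")
    cat = json.loads(blob.decode("utf-8"))
    config = KmerConfig(k=k, n=n, hash_bits=hash_bits)
    catalog = RefCatalog(config=config, n_genomes=cat["n_genomes"])
    for t, info in cat["strains"].items():
        catalog.strains[int(t)] = StrainInfo(
            genus_taxid=info["genus_taxid"],
            species_taxid=info["species_taxid"],
            ref_count=info["ref_count"],
        )
    for t, lin in cat["genera"].items():
        catalog.genera[int(t)] = lin
    return StorageMatrix(hash_bits, slots), catalog


# ---------------------------------------------------------------------------
# end-to-end glue: files -> reference
# ---------------------------------------------------------------------------

def build_reference_from_files(
    assembly_summary: str | Path,
    nodes_dump: str | Path,
    names_dump: str | Path,
    config: KmerConfig,
) -> tuple[StorageMatrix, RefCatalog, TaxonomyTree]:
    """Load taxonomy + assembly summary, label strains (refining conspecific
    unlabelled genomes into convenience strains), profile each genome and
    build the matrix."""
    from .minimizers import profile_fasta
    from .taxonomy import infer_strain_label, load_assembly_summary, load_taxonomy, refine_strains

    tree = load_taxonomy(nodes_dump, names_dump)
    records = load_assembly_summary(assembly_summary, tree)

    strain_of: dict[str, int] = {}
    pending: dict[int, list] = {}
    for rec in records:
        label = infer_strain_label(rec)
        if label is not None:
            strain_of[rec.accession] = label
        else:
            pending.setdefault(rec.species_taxid, []).append(rec)
    for species_taxid in sorted(pending):
        group = pending[species_taxid]
        from .minimizers import read_fasta

        genomes = {
            rec.accession: [seq for _, seq in read_fasta(rec.fasta_path)]
            for rec in group
        }
        assignment = refine_strains(genomes, species_taxid, tree)
        strain_of.update(assignment.strains)

    strain_table: dict[int, list[tuple[str, MinimizerProfile]]] = {}
    for rec in records:
        if rec.accession not in strain_of:
            continue  # ANI outlier dropped during refinement
        profile = profile_fasta(rec.fasta_path, config)
        strain_table.setdefault(strain_of[rec.accession], []).append(
            (rec.accession, profile)
        )
    matrix, catalog = build_reference(strain_table, tree, config)
    return matrix, catalog, tree
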