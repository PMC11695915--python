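"""Taxonomy handling: NCBI-style dumps, eight-rank lineages, strain labels.

The classifier works on an eight-rank ladder (superkingdom, phylum, class,
order, family, genus, species, strain).  "Strain" is treated as any taxid
below species — a descriptive subdivision, with no nomenclatural checks.
Reference genomes whose assembly record carries no sub-species taxid are
given a *convenience strain*: conspecific genomes are sketched, pairwise
ANI is estimated with a MinHash bottom sketch (Mash distance formula), and
clusters at >= 97% ANI each receive a freshly allocated taxid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from sklearn.cluster import DBSCAN

from .minimizers import _encode, _murmur3_32_u64, _packed_nmers, split_ambiguous

__all__ = [
    "RANKS8",
    "TaxNode",
    "Lineage8",
    "TaxonomyTree",
    "TaxonomyParseError",
    "AssemblyRecord",
    "Sketch",
    "StrainAssignment",
    "load_taxonomy",
    "load_assembly_summary",
    "infer_strain_label",
    "minhash_sketch",
    "mash_ani",
    "cluster_by_ani",
    "refine_strains",
    "operative_genus",
]

RANKS8 = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
    "strain",
)

MAX_ALLOCATABLE_TAXID = 2**32 - 2  # 2**32 - 1 is the storage-matrix sentinel


class TaxonomyParseError(ValueError):
    """Malformed or structurally inconsistent taxonomy input."""


@dataclass
class TaxNode:
    taxid: int
    parent: int
    rank: str  # one of RANKS8 or "other"
    name: str = ""


@dataclass
class Lineage8:
    """One optional taxid per rank, superkingdom through strain."""

    superkingdom: Optional[int] = None
    phylum: Optional[int] = None
    class_: Optional[int] = None
    order: Optional[int] = None
    family: Optional[int] = None
    genus: Optional[int] = None
    species: Optional[int] = None
    strain: Optional[int] = None

    _FIELD = {r: (r if r != "class" else "class_") for r in RANKS8}

    def get(self, rank: str) -> Optional[int]:
        return getattr(self, self._FIELD[rank])

    def set(self, rank: str, taxid: int) -> None:
        setattr(self, self._FIELD[rank], taxid)

    def as_dict(self) -> dict[str, Optional[int]]:
        return {r: self.get(r) for r in RANKS8}


class TaxonomyTree:
    """Rank-aware taxid tree with parent links."""

    def __init__(self, nodes: dict[int, TaxNode]):
        self.nodes = nodes
        roots = [n.taxid for n in nodes.values() if n.parent == n.taxid]
        if len(roots) != 1:
            raise TaxonomyParseError(f"expected exactly one root, found {roots}")
        self.root = roots[0]
        self._validate()

    def _validate(self) -> None:
        for node in self.nodes.values():
            if node.parent not in self.nodes:
                raise TaxonomyParseError(
                    f"taxid {node.taxid} has missing parent {node.parent}"
                )
            # walk to root, guarding against cycles
            seen = set()
            cur = node.taxid
            while cur != self.root:
                if cur in seen:
                    raise TaxonomyParseError(f"cycle through taxid {cur}")
                seen.add(cur)
                cur = self.nodes[cur].parent

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def max_taxid(self) -> int:
        return max(self.nodes)

    def name(self, taxid: int) -> str:
        return self.nodes[taxid].name

    def path_to_root(self, taxid: int) -> list[TaxNode]:
        if taxid not in self.nodes:
            raise KeyError(f"unknown taxid {taxid}")
        chain = [self.nodes[taxid]]
        while chain[-1].taxid != self.root:
            chain.append(self.nodes[chain[-1].parent])
        return chain

    def lineage8(self, taxid: int) -> Lineage8:
        """Fill the eight rank slots walking from taxid to the root.

        The most specific occurrence of each rank wins.  An unranked node
        sitting below a species on the chain fills the strain slot.
        """
        chain = self.path_to_root(taxid)
        lineage = Lineage8()
        species_depth = next(
            (i for i, node in enumerate(chain) if node.rank == "species"), None
        )
        for i, node in enumerate(chain):
            if node.rank in RANKS8:
                if lineage.get(node.rank) is None:
                    lineage.set(node.rank, node.taxid)
            elif (
                species_depth is not None
                and i < species_depth
                and lineage.strain is None
            ):
                lineage.strain = node.taxid
        return lineage

    def add_strain(self, taxid: int, species_taxid: int, name: str = "") -> None:
        """Register a convenience strain node under an existing species."""
        if taxid in self.nodes:
            raise ValueError(f"taxid {taxid} already present")
        if species_taxid not in self.nodes:
            raise KeyError(f"unknown species taxid {species_taxid}")
        self.nodes[taxid] = TaxNode(taxid, species_taxid, "strain", name)


def _parse_dump_rows(path: str | Path, min_fields: int) -> Iterable[tuple[int, list[str]]]:
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.endswith("\t|"):
                line = line[: -len("\t|")]
            fields = line.split("\t|\t")
            if len(fields) < min_fields:
                raise TaxonomyParseError(
                    f"{path}: line {lineno}: expected >= {min_fields} fields, "
                    f"got {len(fields)}"
                )
            yield lineno, fields


def load_taxonomy(nodes_dump: str | Path, names_dump: str | Path) -> TaxonomyTree:
    """Parse pipe-delimited nodes/names dumps into a TaxonomyTree.

    Ranks outside the eight-rank ladder are retained as "other" so the
    chain stays traversable.
    """
    nodes: dict[int, TaxNode] = {}
    for _, fields in _parse_dump_rows(nodes_dump, 3):
        taxid = int(fields[0])
        parent = int(fields[1])
        rank = fields[2].strip()
        nodes[taxid] = TaxNode(taxid, parent, rank if rank in RANKS8 else "other")
    for _, fields in _parse_dump_rows(names_dump, 2):
        taxid = int(fields[0])
        name_class = fields[3].strip() if len(fields) > 3 else "scientific name"
        if taxid in nodes and name_class == "scientific name":
            nodes[taxid].name = fields[1].strip()
    return TaxonomyTree(nodes)


# ---------------------------------------------------------------------------
# assembly summary
# ---------------------------------------------------------------------------

@dataclass
class AssemblyRecord:
    """One reference genome: accession, lowest taxid, species taxid, FASTA path."""

    accession: str
    taxid: int
    species_taxid: int
    fasta_path: Path


def load_assembly_summary(path: str | Path, tree: TaxonomyTree) -> list[AssemblyRecord]:
    """Read a tab-delimited assembly summary ('#' header lines).

    Requires columns assembly_accession, taxid, species_taxid, local_path;
    both taxids must resolve in the tree.
    """
    path = Path(path)
    header: Optional[list[str]] = None
    records: list[AssemblyRecord] = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                header = line.lstrip("# ").split("\t")
                continue
            if header is None:
                raise TaxonomyParseError(f"{path}: missing '#' header line")
            row = dict(zip(header, line.split("\t")))
            missing = {"assembly_accession", "taxid", "species_taxid", "local_path"} - set(row)
            if missing:
                raise TaxonomyParseError(f"{path}: missing columns {sorted(missing)}")
            rec = AssemblyRecord(
                accession=row["assembly_accession"],
                taxid=int(row["taxid"]),
                species_taxid=int(row["species_taxid"]),
                fasta_path=Path(row["local_path"]),
            )
            for t in (rec.taxid, rec.species_taxid):
                if t not in tree:
                    raise TaxonomyParseError(
                        f"{path}: accession {rec.accession}: taxid {t} not in taxonomy"
                    )
            records.append(rec)
    return records


def infer_strain_label(record: AssemblyRecord) -> Optional[int]:
    """Strain taxid if the record's lowest taxid is below species, else None.

    None marks the record for refine_strains (convenience-strain allocation).
    """
    if record.taxid != record.species_taxid:
        return record.taxid
    return None


# ---------------------------------------------------------------------------
# MinHash sketching and ANI
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Sketch:
    """Bottom-s MinHash sketch of canonical k-mer hashes, sorted ascending."""

    kmer_len: int
    size: int
    hashes: np.ndarray

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Sketch):
            return NotImplemented
        return (
            self.kmer_len == other.kmer_len
            and self.size == other.size
            and np.array_equal(self.hashes, other.hashes)
        )


def minhash_sketch(
    sequences: Iterable[str], kmer_len: int = 21, size: int = 1000
) -> Sketch:
    """Bottom-`size` sketch over canonical k-mers of a genome.

    Canonical k-mer = the smaller of the packed forward and reverse-
    complement encodings; both strands therefore sketch identically.
    Genomes with fewer than `size` distinct k-mers yield smaller sketches.
    """
    if not (1 <= kmer_len <= 31):
        raise ValueError("kmer_len must be in [1, 31]")
    chunks: list[np.ndarray] = []
    n_seqs = 0
    for seq in sequences:
        n_seqs += 1
        for fragment in split_ambiguous(seq, kmer_len):
            codes = _encode(fragment)
            fwd = _packed_nmers(codes, kmer_len)
            rev = _packed_nmers((np.uint8(3) - codes)[::-1], kmer_len)
            canonical = np.minimum(fwd, rev[::-1])
            chunks.append(_murmur3_32_u64(canonical << np.uint64(2)))
    if n_seqs == 0 or not chunks:
        raise ValueError("cannot sketch an empty genome")
    distinct = np.unique(np.concatenate(chunks))
    return Sketch(kmer_len=kmer_len, size=size, hashes=distinct[:size])


def mash_ani(a: Sketch, b: Sketch) -> float:
    """ANI percentage estimated from two sketches via the Mash distance.

    Jaccard j is taken over the bottom-s merged sketch; then
    d = -(1/k) * ln(2j / (1 + j)) and ANI = max(0, 1 - d) * 100.
    j = 0 maps to ANI 0.
    """
    if a.kmer_len != b.kmer_len or a.size != b.size:
        raise ValueError("sketch parameter mismatch")
    union = np.union1d(a.hashes, b.hashes)
    s = min(a.size, union.size)
    if s == 0:
        return 0.0
    bottom = union[:s]
    shared = np.intersect1d(np.intersect1d(bottom, a.hashes), b.hashes).size
    j = shared / s
    if j <= 0.0:
        return 0.0
    d = -np.log(2.0 * j / (1.0 + j)) / a.kmer_len
    return float(np.clip((1.0 - d) * 100.0, 0.0, 100.0))


# ---------------------------------------------------------------------------
# strain refinement
# ---------------------------------------------------------------------------

@dataclass
class StrainAssignment:
    """accession -> strain taxid, plus the convenience taxids minted on the way."""

    strains: dict[str, int] = field(default_factory=dict)
    allocated_ids: set[int] = field(default_factory=set)
    outliers: set[str] = field(default_factory=set)


def cluster_by_ani(
    ani: np.ndarray,
    *,
    ani_cluster: float = 97.0,
    ani_outlier: float = 50.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Density-cluster genomes on an ANI percentage matrix.

    Returns (labels, kept): `kept` is a boolean mask of non-outlier rows
    (max off-diagonal ANI >= ani_outlier; a lone genome is always kept),
    `labels` assigns every kept genome a cluster (min_samples = 1, so no
    genome is left as noise).  eps on the 1 - ANI/100 distance equals
    1 - ani_cluster/100.
    """
    ani = np.asarray(ani, dtype=float)
    n = ani.shape[0]
    if n == 1:
        return np.zeros(1, dtype=int), np.ones(1, dtype=bool)
    off_diag = ani.copy()
    np.fill_diagonal(off_diag, -np.inf)
    kept = off_diag.max(axis=1) >= ani_outlier
    if n > 1 and kept.sum() == 0:
        # mutually dissimilar genomes: each is its own cluster, none dropped
        kept = np.ones(n, dtype=bool)
    dist = 1.0 - ani[np.ix_(kept, kept)] / 100.0
    np.fill_diagonal(dist, 0.0)
    eps = 1.0 - ani_cluster / 100.0
    labels = DBSCAN(eps=eps, min_samples=1, metric="precomputed").fit_predict(dist)
    return labels, kept


def refine_strains(
    genomes: Mapping[str, Sequence[str]] | Mapping[str, Sketch],
    species_taxid: int,
    tree: TaxonomyTree,
    *,
    kmer_len: int = 21,
    sketch_size: int = 1000,
    ani_cluster: float = 97.0,
    ani_outlier: float = 50.0,
    next_taxid: Optional[int] = None,
) -> StrainAssignment:
    """Allocate convenience strains to conspecific genomes lacking labels.

    Genomes (accession -> sequences, or precomputed Sketch) are pairwise
    compared by MinHash ANI; genomes whose best ANI against all the others
    is below `ani_outlier` are excluded; the rest are density-clustered at
    `ani_cluster`% similarity and each cluster is given a fresh taxid,
    allocated ascending from max(existing taxids) + 1 and registered in the
    tree as a strain under `species_taxid`.
    """
    accessions = sorted(genomes)
    if not accessions:
        raise ValueError("no genomes to refine")
    sketches = []
    for acc in accessions:
        g = genomes[acc]
        sketches.append(
            g if isinstance(g, Sketch) else minhash_sketch(g, kmer_len, sketch_size)
        )
    n = len(accessions)
    ani = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            ani[i, j] = ani[j, i] = mash_ani(sketches[i], sketches[j])
    labels, kept = cluster_by_ani(ani, ani_cluster=ani_cluster, ani_outlier=ani_outlier)

    assignment = StrainAssignment()
    assignment.outliers = {a for a, keep in zip(accessions, kept) if not keep}
    kept_accs = [a for a, keep in zip(accessions, kept) if keep]
    taxid_cursor = (tree.max_taxid + 1) if next_taxid is None else next_taxid
    cluster_taxid: dict[int, int] = {}
    for acc, label in zip(kept_accs, labels):
        if label not in cluster_taxid:
            if taxid_cursor > MAX_ALLOCATABLE_TAXID:
                raise RuntimeError("convenience taxid space exhausted")
            cluster_taxid[label] = taxid_cursor
            tree.add_strain(
                taxid_cursor, species_taxid, name=f"convenience strain {taxid_cursor}"
            )
            assignment.allocated_ids.add(taxid_cursor)
            taxid_cursor += 1
        assignment.strains[acc] = cluster_taxid[label]
    return assignment


def operative_genus(lineage: Lineage8) -> int:
    """Most specific rank in the family..superkingdom interval, as a stand-in
    genus for lineages that lack one."""
    if lineage.genus is not None:
        raise ValueError("lineage already has a genus")
    for rank in ("family", "order", "class", "phylum", "superkingdom"):
        taxid = lineage.get(rank)
        if taxid is not None:
            return taxid
    raise ValueError("empty lineage: no rank available as operative genus")
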