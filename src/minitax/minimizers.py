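"""k-mer/minimizer counting for nucleotide sequences.

Every genome and every query bin is reduced to a multiset of 32-bit
minimizer hashes: each k-mer window (default k = 61) is represented by its
lexicographically smallest n-mer (default n = 31, A < C < G < T), the n-mer
is 2-bit packed into a 64-bit word and digested with murmur3-x86_32.  Both
the forward sequence and its reverse complement are enumerated, so profiles
are strand-symmetric by construction.

The hot path is fully vectorized over numpy arrays; the scalar functions
(`minimizer_of_kmer`, `pack_2bit`, `hash_minimizer`, `murmur3_32`) define
the semantics one symbol at a time and serve as the readable contract.
"""

from __future__ import annotations

import gzip
import re
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "KmerConfig",
    "MinimizerProfile",
    "split_ambiguous",
    "reverse_complement",
    "minimizer_of_kmer",
    "pack_2bit",
    "hash_minimizer",
    "murmur3_32",
    "extract_minimizers",
    "profile_genome",
    "profile_fasta",
    "read_fasta",
]

_ACGT_SPLIT = re.compile(r"[^ACGT]+")
_RC_TABLE = str.maketrans("ACGT", "TGCA")
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

# byte-value -> 2-bit code lookup; 255 marks invalid symbols
_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _c in _BASE_CODE.items():
    _CODE_LUT[ord(_b)] = _c


@dataclass(frozen=True)
class KmerConfig:
    """Lengths governing minimizer extraction.

    k: k-mer window length in nt.
    n: minimizer length in nt; must fit 62 bits when 2-bit packed (n <= 31).
    hash_bits: width h of the addressable slot space, slots = 2**h.
        h = 32 is the full matrix; smaller h folds hashes modulo 2**h.
    """

    k: int = 61
    n: int = 31
    hash_bits: int = 32

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError(f"k must be >= 2, got {self.k}")
        if not (1 <= self.n <= 31):
            raise ValueError(f"n must be in [1, 31], got {self.n}")
        if self.n >= self.k:
            raise ValueError(f"n must be < k, got n={self.n}, k={self.k}")
        if not (1 <= self.hash_bits <= 32):
            raise ValueError(f"hash_bits must be in [1, 32], got {self.hash_bits}")


class MinimizerProfile:
    """Multiset of 32-bit minimizer hashes for a sequence set.

    Stored as a sorted unique hash array plus parallel occurrence counts;
    `distinct` is the key set view the reference builder consumes.
    """

    __slots__ = ("hashes", "counts")

    def __init__(self, hashes: np.ndarray, counts: np.ndarray) -> None:
        self.hashes = np.asarray(hashes, dtype=np.uint32)
        self.counts = np.asarray(counts, dtype=np.int64)
        if self.hashes.shape != self.counts.shape:
            raise ValueError("hashes and counts must be parallel arrays")

    @classmethod
    def empty(cls) -> "MinimizerProfile":
        return cls(np.empty(0, dtype=np.uint32), np.empty(0, dtype=np.int64))

    @classmethod
    def from_multiset(cls, raw_hashes: np.ndarray) -> "MinimizerProfile":
        hashes, counts = np.unique(np.asarray(raw_hashes, dtype=np.uint32), return_counts=True)
        return cls(hashes, counts.astype(np.int64))

    @property
    def distinct(self) -> np.ndarray:
        """Sorted array of distinct minimizer hashes."""
        return self.hashes

    @property
    def n_distinct(self) -> int:
        return int(self.hashes.size)

    @property
    def total_occurrences(self) -> int:
        return int(self.counts.sum())

    def as_dict(self) -> dict[int, int]:
        return {int(h): int(c) for h, c in zip(self.hashes, self.counts)}

    def merge(self, other: "MinimizerProfile") -> "MinimizerProfile":
        """Union with summed occurrences."""
        cat = np.concatenate([self.hashes, other.hashes])
        cnt = np.concatenate([self.counts, other.counts])
        hashes, inv = np.unique(cat, return_inverse=True)
        counts = np.zeros(hashes.size, dtype=np.int64)
        np.add.at(counts, inv, cnt)
        return MinimizerProfile(hashes, counts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MinimizerProfile):
            return NotImplemented
        return np.array_equal(self.hashes, other.hashes) and np.array_equal(
            self.counts, other.counts
        )

    def __len__(self) -> int:
        return self.n_distinct

    def __repr__(self) -> str:
        return (
            f"MinimizerProfile(n_distinct={self.n_distinct}, "
            f"total={self.total_occurrences})"
        )


# ---------------------------------------------------------------------------
# scalar contract
# ---------------------------------------------------------------------------

def split_ambiguous(seq: str, k: int) -> list[str]:
    """Split at non-ACGT symbols and drop fragments shorter than k.

    Input is case-insensitive; any IUPAC ambiguity code (N, R, Y, ...) or
    other symbol breaks the sequence.  Fragments are returned uppercased,
    in original order.
    """
    return [f for f in _ACGT_SPLIT.split(seq.upper()) if len(f) >= k]


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of an ACGT-only string."""
    up = seq.upper()
    if _ACGT_SPLIT.search(up):
        raise ValueError("non-ACGT symbol in sequence; split_ambiguous first")
    return up.translate(_RC_TABLE)[::-1]


def minimizer_of_kmer(kmer: str, n: int) -> str:
    """Lexicographically smallest n-long substring (A<C<G<T), leftmost on ties."""
    if len(kmer) < n:
        raise ValueError(f"k-mer shorter than minimizer length {n}")
    # min() keeps the first minimal element, i.e. the leftmost occurrence
    return min(kmer[i : i + n] for i in range(len(kmer) - n + 1))


def pack_2bit(nmer: str) -> int:
    """2-bit pack an n-mer (A=00 C=01 G=10 T=11), first base most significant,
    then shift left by 2 so bit positions 0 and 1 carry the '00' offset."""
    if len(nmer) > 31:
        raise ValueError(f"n-mer longer than 31 nt: {len(nmer)}")
    value = 0
    for base in nmer:
        try:
            value = (value << 2) | _BASE_CODE[base]
        except KeyError:
            raise ValueError(f"non-ACGT symbol {base!r} in n-mer") from None
    return value << 2


_C1 = 0xCC9E2D51
_C2 = 0x1B873593
_MASK32 = 0xFFFFFFFF


def murmur3_32(data: bytes, seed: int = 0) -> int:
    """murmur3-x86_32 digest of a byte string, unsigned."""
    h = seed & _MASK32
    n_blocks = len(data) // 4
    for i in range(n_blocks):
        k = int.from_bytes(data[4 * i : 4 * i + 4], "little")
        k = (k * _C1) & _MASK32
        k = ((k << 15) | (k >> 17)) & _MASK32
        k = (k * _C2) & _MASK32
        h ^= k
        h = ((h << 13) | (h >> 19)) & _MASK32
        h = (h * 5 + 0xE6546B64) & _MASK32
    tail = data[4 * n_blocks :]
    k = 0
    for i, byte in enumerate(tail):
        k |= byte << (8 * i)
    if tail:
        k = (k * _C1) & _MASK32
        k = ((k << 15) | (k >> 17)) & _MASK32
        k = (k * _C2) & _MASK32
        h ^= k
    h ^= len(data)
    h ^= h >> 16
    h = (h * 0x85EBCA6B) & _MASK32
    h ^= h >> 13
    h = (h * 0xC2B2AE35) & _MASK32
    h ^= h >> 16
    return h


def hash_minimizer(nmer: str) -> int:
    """32-bit murmur3 (seed 0) of the packed n-mer serialized little-endian."""
    return murmur3_32(struct.pack("<Q", pack_2bit(nmer)), seed=0)


# ---------------------------------------------------------------------------
# vectorized engine
# ---------------------------------------------------------------------------

def _encode(fragment: str) -> np.ndarray:
    """ACGT fragment -> uint8 code array (caller guarantees purity)."""
    raw = np.frombuffer(fragment.encode("ascii"), dtype=np.uint8)
    codes = _CODE_LUT[raw]
    if codes.max(initial=0) == 255:
        raise ValueError("non-ACGT symbol in fragment")
    return codes


def _packed_nmers(codes: np.ndarray, n: int) -> np.ndarray:
    """Packed 2n-bit values of every n-long window, as uint64 (no offset shift)."""
    m = codes.size - n + 1
    if m <= 0:
        return np.empty(0, dtype=np.uint64)
    packed = np.zeros(m, dtype=np.uint64)
    wide = codes.astype(np.uint64)
    for j in range(n):
        packed = (packed << np.uint64(2)) | wide[j : j + m]
    return packed


def _murmur3_32_u64(values: np.ndarray, seed: int = 0) -> np.ndarray:
    """Vectorized murmur3-x86_32 over uint64 values serialized 8-byte LE."""
    v = values.astype(np.uint64)
    h = np.full(v.shape, np.uint32(seed), dtype=np.uint32)
    c1 = np.uint32(_C1)
    c2 = np.uint32(_C2)
    for block in ((v & np.uint64(_MASK32)), (v >> np.uint64(32))):
        k = block.astype(np.uint32)
        k *= c1
        k = (k << np.uint32(15)) | (k >> np.uint32(17))
        k *= c2
        h ^= k
        h = (h << np.uint32(13)) | (h >> np.uint32(19))
        h = h * np.uint32(5) + np.uint32(0xE6546B64)
    h ^= np.uint32(8)  # total length in bytes
    h ^= h >> np.uint32(16)
    h *= np.uint32(0x85EBCA6B)
    h ^= h >> np.uint32(13)
    h *= np.uint32(0xC2B2AE35)
    h ^= h >> np.uint32(16)
    return h


def _fragment_hashes(codes: np.ndarray, config: KmerConfig) -> np.ndarray:
    """Minimizer hash of every k-mer window of one coded strand."""
    if codes.size < config.k:
        return np.empty(0, dtype=np.uint32)
    packed = _packed_nmers(codes, config.n)
    w = config.k - config.n + 1
    # numeric order of fixed-length packed values == lexicographic order
    windows = np.lib.stride_tricks.sliding_window_view(packed, w)
    minimizers = windows.min(axis=1)
    return _murmur3_32_u64(minimizers << np.uint64(2))


def extract_minimizers(seq: str, config: KmerConfig) -> MinimizerProfile:
    """Minimizer profile of one sequence, both strands.

    Each ACGT fragment contributes len(fragment) - k + 1 occurrences per
    strand; occurrences accumulate with multiplicity.
    """
    chunks: list[np.ndarray] = []
    for fragment in split_ambiguous(seq, config.k):
        codes = _encode(fragment)
        chunks.append(_fragment_hashes(codes, config))
        chunks.append(_fragment_hashes((np.uint8(3) - codes)[::-1], config))
    if not chunks:
        return MinimizerProfile.empty()
    return MinimizerProfile.from_multiset(np.concatenate(chunks))


def profile_genome(records: Iterable[str], config: KmerConfig) -> MinimizerProfile:
    """Profile of a genome given as its sequence records; occurrences sum."""
    chunks: list[np.ndarray] = []
    n_records = 0
    for seq in records:
        n_records += 1
        for fragment in split_ambiguous(seq, config.k):
            codes = _encode(fragment)
            chunks.append(_fragment_hashes(codes, config))
            chunks.append(_fragment_hashes((np.uint8(3) - codes)[::-1], config))
    if n_records == 0:
        raise ValueError("no sequence records supplied")
    if not chunks:
        return MinimizerProfile.empty()
    return MinimizerProfile.from_multiset(np.concatenate(chunks))


# ---------------------------------------------------------------------------
# FASTA plumbing
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (optionally gzipped) FASTA file as [(record_id, sequence)].

    Record IDs are the first whitespace-delimited header token.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:  # type: ignore[operator]
        return [(header.split()[0], seq) for header, seq in SimpleFastaParser(handle)]


def profile_fasta(path: str | Path, config: KmerConfig) -> MinimizerProfile:
    """Profile every record of a FASTA file; empty file is an error."""
    records = read_fasta(path)
    if not records:
        raise ValueError(f"empty FASTA file: {path}")
    return profile_genome((seq for _, seq in records), config)
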