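# Methods

## Model and assumptions

minitax classifies MAGs by exact sharing of minimizer hashes with reference
genomes. The working assumption is the standard minimizer argument: if two
sequences are locally similar, at least one minimizer chosen from one will
occur in the other, so strain- or genus-exclusive minimizers are a usable
fingerprint. The method is purely compositional — no alignment, no
phylogenetic placement — so its resolution is bounded by how exclusive the
reference minimizer sets are: taxa absent from the reference can only be
absorbed by their nearest represented relative or rejected by the ass2ref
filter.

### Minimizer extraction

- k-mer length **k = 61**, minimizer length **n = 31** (defaults).
  n ≤ 31 so the 2-bit-packed minimizer (62 bits) fits an 8-byte word with a
  00 offset in the two least significant bits.
- Ordering is plain lexicographic with A < C < G < T. Because the packing
  is order-preserving for fixed-length strings, the numeric minimum of the
  packed windows equals the lexicographic minimum — this is what the
  vectorized engine computes. Ties between equal minimal strings resolve to
  the leftmost window; equal strings hash identically, so this fixes
  provenance only.
- Both the forward fragment and its reverse complement are enumerated in
  full (no canonical-kmer selection); deduplication happens only in the
  distinct-set view. An ACGT fragment of length L contributes
  2·(L − k + 1) occurrences.
- Any non-ACGT symbol (N or other IUPAC codes, case-insensitive) splits the
  sequence; fragments shorter than k are dropped.
- Hash: murmur3-x86_32, seed 0, over the packed value serialized as 8-byte
  little-endian. The dialect (seed, endianness, variant) is centralized in
  one function so a single constant switches it; we claim internal
  consistency, not bit-compatibility with any other binary artifact. The
  scalar implementation is cross-checked in the test suite against
  scikit-learn's murmurhash3_32, and the vectorized path against the
  scalar.

### Storage matrix

2^h slots of 4 bytes (h = 32 full scale: 17 179 869 184 bytes). Slot
address = hash at h = 32, hash mod 2^h below; row = address ÷ 8,
column = address mod 8. Fill transitions per incoming (strain s, genus g):

| current slot | result |
|---|---|
| empty | s |
| black | black |
| s | s |
| other strain of g, or g itself | g |
| anything of another genus | black |

The slot fixpoint depends only on the *set* of (strain, genus) pairs that
reach it — more than one genus ⇒ black, else more than one strain ⇒ genus,
else strain — so builds are order-invariant (tested over permutations).
The demotion of a slot shared by two conspecific strains to their genus
taxid is implied by the four-state design; it is what makes genus-level
evidence accumulate. Only the representative genome per strain (distinct
count nearest the median; ties → smaller count, then lexicographic
accession) inserts minimizers; multiplicities play no role at build time.
Two different minimizers may collide in one 32-bit hash or (for h < 32) in
one slot; this is accepted silently. EMPTY = 0 and BLACK = 2^32 − 1 are
reserved, so convenience-taxid allocation caps at 2^32 − 2.

### Strain labelling and refinement

An assembly record whose `taxid` differs from its `species_taxid` is taken
as already strain-labelled. Unlabelled conspecific genomes are compared by
MinHash ANI (bottom-1000 sketch of canonical 21-mers, the cited sketching
tool's defaults; Jaccard from the merged bottom sketch, then
d = −ln(2j/(1+j))/k, ANI = max(0, 1 − d)·100, clamped to [0, 100], j = 0 →
0). A genome whose best ANI against all its conspecifics is below 50% is
dropped as an outlier; we read the 50% rule as one-vs-all maximum since the
reference text does not say against what (if *every* genome of a species
fails it, we keep them all rather than orphan the species — mutual
dissimilarity then just yields singleton clusters). Survivors are
DBSCAN-clustered on 1 − ANI/100 with eps = 0.03 and min_samples = 1, so
every genome lands in a cluster and singletons are legitimate convenience
strains; each cluster receives a fresh taxid allocated globally ascending
from max(existing) + 1. Strains whose lineage lacks a genus rank fall back
to the *operative genus*: the most specific available rank among
family, order, class, phylum, superkingdom.

### Classification

The resume table aggregates per *slot address*, not per raw hash: the
matrix cannot distinguish two hashes that share a slot, and counting slots
makes the self-query ass2ref exactly 1 and keeps the ratio naturally
bounded (any residual inflation is capped at 1 and counted in the log).
Prevalence uses occurrence multiplicities (strain hits roll up to their
genus); ass2ref uses distinct slot counts over the strain's surviving
`ref_count`, with ref_count 0 guarded to 0. All argmax ties break toward
the smaller taxid, making runs byte-deterministic. Species exists only as
an aggregation of strain evidence — a bin with genus-rank hits alone gets
a genus-only call with ass2ref 0. Below the threshold (default 0.2, the
suggested operating point) species/strain are cleared and the genus-level
call is retained; unclassified bins (empty resume table) are logged and
omitted from the CSV.

### Evaluation

Confusion counts are set-based per rank: Tp = |C_O ∩ C_E|,
Fp = |C_O| − Tp, Fn = |C_E| − Tp and Tn = |C_T| − |C_O ∪ C_E|, which
partitions the taxon universe; metrics are percentages, 0/0 is reported as
undefined rather than 0, and printed values round half-up to 2 decimals.
The bundled real-mock benchmark counts are a worked example for the metric
arithmetic; the package recomputes every metric from the counts and never
stores a metric value it did not derive.

## Synthetic fixtures

The generator emulates the real inputs (genome FASTA, nodes/names dumps,
assembly summary, truth table) with substitution-only evolution: a root
genome, genus ancestors at the between-genus rate (default 0.10), species
at 0.03, strains at 0.005, i.i.d. positions, no indels. Consequently
ANI ≈ (1 − r)·100 holds in closed form, which the parameter-recovery tests
exploit. What this does *not* emulate: indels and rearrangements, real
genome length and repeat structure, horizontal transfer, chimeric or
contaminated bins, and sequencing error models — so green tests show the
pipeline's logic and determinism, not field accuracy on real MAGs.
Fixture references default to reduced hash widths (h = 20–24, 4–64 MiB)
purely to keep matrices desk-sized; h is stored in every serialized
reference so mixing widths fails loudly. The acceptance cohort is
3 genera × 2 species × 2 strains at 50 kb and h = 24; order-invariance
uses twenty 2×1×2 clades at 4 kb and h = 20.

## Numerical and design choices

- Packing puts the first base in the most significant bit pair; only the
  code table and the low-order 00 offset are externally fixed.
- Sliding-window minima use a strided view (window w = k − n + 1 ≤ 31), so
  extraction is O(L·n/word) vectorized; the quadratic enumeration oracle in
  the tests defines the semantics independently.
- Serialization is a fixed little-endian layout (magic `MTAXREF1`, version,
  k/n/h, raw slots, length-prefixed JSON catalogue); load is bit-exact and
  refuses foreign magic, foreign versions and truncation distinctly.
- Degenerate inputs: empty FASTA errors with the file name; all-ambiguous
  records contribute nothing; a sequence shorter than k yields an empty
  profile; an empty resume table is "unclassified", never a guess.

## Known limitations

- No incremental reference updates; rebuild only. No compression.
- No contig- or read-level classification and no abundance estimation.
- Genus calls for taxa missing from the reference are best-effort
  absorption; the ass2ref filter reduces, but cannot eliminate, false
  strain assignments for unrepresented taxa.
- The full h = 32 matrix needs ~17 GB plus catalogue; building real-scale
  references is memory-bound by design.
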