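# minitax

Alignment-free taxonomic classification of metagenome-assembled genomes
(MAGs) at genus, species and strain level, for microbiome researchers who
bin metagenomic assemblies and need fast, reference-based labels.

## Method

**Reference.** Every reference genome is reduced to a set of 32-bit
*minimizer hashes*: each k-mer window (k = 61) is represented by its
lexicographically smallest n-mer (n = 31, A < C < G < T), 2-bit packed
(A=00, C=01, G=10, T=11, with a 00 offset in the two low bits) and digested
with murmur3-x86_32. Both strands are enumerated, so profiles are
strand-symmetric. Hashes address a flat **storage matrix** of 2^h unsigned
32-bit slots (h = 32 by default: 2^29 rows × 8 columns, 4 × 2^32 ≈ 17 GB;
smaller h folds hashes modulo 2^h for desk-scale work). One representative
genome per strain — the one whose distinct-minimizer count is nearest the
strain's median — fills the matrix: an empty slot takes the strain taxid, a
slot re-hit by a second strain of the same genus demotes to the genus
taxid, and a slot hit by two genera is *blacked* (redundant, absorbing).
Genomes that arrive without a sub-species taxid get a **convenience
strain**: conspecific genomes are MinHash-sketched (k = 21, bottom-1000),
pairwise ANI is estimated with the Mash distance
`d = -ln(2j/(1+j))/k`, genomes with best ANI < 50% are dropped as
outliers, and DBSCAN clusters at ≥ 97% ANI each receive a fresh taxid.

**Classification.** A query bin is shredded into q-minimizers the same
way; non-sentinel slot hits accumulate into a resume table
(taxid → occurrences, distinct slots, rank). The call is prevalence-based:
most abundant genus (strain hits roll up to their genus), most abundant
species within it, then the strain maximizing

    ass2ref = distinct observed strain minimizers / strain reference minimizers

a confidence ratio in [0, 1]. Below the suggested threshold of 0.2 the
species/strain fields are dropped and the call is genus-only. Output is a
CSV with one line per classified bin: bin name, ass2ref, assigned taxid,
the species…superkingdom taxids and the organism name.

**Evaluation.** Observed vs expected taxa are scored per rank as sets over
the reference taxonomy: Tp = |C_O ∩ C_E|, Fp = |C_O| − Tp,
Fn = |C_E| − Tp, Tn = |C_T| − |C_O ∪ C_E|, feeding sensitivity, precision,
FPR, balanced accuracy and F1 (percentages).

## Worked example

Generate a synthetic clade (2 genera × 2 species × 2 strains, 20 kb
genomes), build a reference at h = 20, and classify two of the genomes as
bins:

```sh
minitax make-fixture --out demo --genera 2 --species 2 --strains 2 --length 20000 --seed 7
minitax build-ref --summary demo/assembly_summary.tsv --nodes demo/nodes.dmp \
    --names demo/names.dmp --out demo/ref.bin --hash-bits 20
mkdir demo/bins && cp demo/genomes/SYN_100_1000_10000.fa demo/genomes/SYN_101_1002_10004.fa demo/bins/
minitax classify --reference demo/ref.bin --bins demo/bins --a2r 0.2 \
    --out demo/calls.csv --nodes demo/nodes.dmp --names demo/names.dmp
cat demo/calls.csv
```

```
bin_name,ass2ref,taxid,species_taxid,genus_taxid,family_taxid,order_taxid,class_taxid,phylum_taxid,superkingdom_taxid,organism_name
SYN_100_1000_10000,1.0000,10000,1000,100,,,,,2,Strain 10000
SYN_101_1002_10004,1.0000,10004,1002,101,,,,,2,Strain 10004
```

Each bin recovers its own strain taxid with ass2ref 1.0000: every one of
the strain's reference minimizers was observed in the bin, the strongest
possible evidence. The species/genus columns carry the strain's lineage;
family–phylum are empty because the synthetic taxonomy defines only
superkingdom → genus → species → strain. `minitax evaluate` then scores a
calls CSV against a truth table and prints the per-rank confusion counts
and metrics as TSV.

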