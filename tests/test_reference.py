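"""Storage-matrix build, slot state machine, serialization."""

import itertools

import numpy as np
import pytest

import minitax as mt
from minitax.reference import ReferenceFormatError

from conftest import strain_table_of


def profile_of(seq, config):
    return mt.profile_genome([seq], config)


def toy_tree(tmp_path, n_genera=2, species_per_genus=1, strains_per_species=2):
    spec = mt.FixtureSpec(
        n_genera=n_genera,
        species_per_genus=species_per_genus,
        strains_per_species=strains_per_species,
        genome_length=2_000,
        seed=1,
    )
    clade = mt.make_clade(spec, out_dir=tmp_path)
    return clade, mt.load_taxonomy(clade.nodes_dump, clade.names_dump)


# ---------------------------------------------------------------------------
# geometry and representative selection
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "m,expected", [(0, (0, 0)), (17, (2, 1)), (2**32 - 1, (2**29 - 1, 7))]
)
def test_slot_coords(m, expected):
    row, col = mt.slot_coords(m, 32)
    assert (row, col) == expected
    assert row * 8 + col == m


def test_address_of_identity_and_reduction():
    assert mt.address_of(5, 32) == 5
    assert mt.address_of(2**20 + 3, 10) == 3
    arr = np.arange(100, dtype=np.uint32)
    assert np.array_equal(mt.address_of(arr, 32), arr)
    assert np.array_equal(mt.address_of(arr, 4), arr % 16)


def test_matrix_footprint():
    assert mt.matrix_footprint(32) == 17_179_869_184
    assert mt.matrix_footprint(3) == 32
    assert mt.matrix_footprint(32) // 8 // 4 == 2**29  # rows at h = 32


def test_select_representative_median_rule(small_config):
    def fake(count, acc):
        # distinct minimizer count == number of distinct hashes
        hashes = np.arange(count, dtype=np.uint32)
        return acc, mt.MinimizerProfile(hashes, np.ones(count, dtype=np.int64))

    assert mt.select_representative([fake(10, "a"), fake(12, "b"), fake(20, "c")]) == "b"
    assert mt.select_representative([fake(10, "a"), fake(20, "b")]) == "a"
    assert mt.select_representative([fake(7, "only")]) == "only"
    # equal counts: lexicographically smallest accession
    assert mt.select_representative([fake(5, "z"), fake(5, "a")]) == "a"
    with pytest.raises(ValueError):
        mt.select_representative([])


# ---------------------------------------------------------------------------
# slot state machine
# ---------------------------------------------------------------------------

S1, S2, G1, G2 = 101, 102, 11, 12


@pytest.mark.parametrize(
    "current,strain,genus,genus_of_current,expected",
    [
        (mt.EMPTY, S1, G1, None, S1),
        (mt.BLACK, S1, G1, None, mt.BLACK),
        (S1, S1, G1, G1, S1),
        (S1, S2, G1, G1, G1),        # sibling strain: demote to genus
        (S1, S2, G2, G1, mt.BLACK),  # different genus: black
        (G1, S2, G1, G1, G1),        # same genus keeps the slot
        (G1, S2, G2, G1, mt.BLACK),  # second genus blacks
    ],
)
def test_update_slot_transitions(current, strain, genus, genus_of_current, expected):
    assert mt.update_slot(current, strain, genus, genus_of_current) == expected


def test_update_slot_rejects_sentinel_taxids():
    with pytest.raises(ValueError):
        mt.update_slot(mt.EMPTY, mt.BLACK, G1)
    with pytest.raises(ValueError):
        mt.update_slot(mt.EMPTY, S1, mt.EMPTY)


def test_black_is_absorbing_under_any_sequence():
    state = mt.EMPTY
    for strain, genus, gcur in [(S1, G1, None), (S2, G2, G1), (S1, G1, None)]:
        state = mt.update_slot(state, strain, genus, gcur)
    assert state == mt.BLACK


# ---------------------------------------------------------------------------
# build
# ---------------------------------------------------------------------------

def test_build_single_strain_all_slots_strain(tmp_path, small_config):
    clade, tree = toy_tree(tmp_path, n_genera=1, strains_per_species=1)
    g = clade.genomes[0]
    profile = profile_of(g.sequence, small_config)
    table = {g.strain_taxid: [(g.accession, profile)]}
    matrix, catalog = mt.build_reference(table, tree, small_config)
    n_addr = np.unique(mt.address_of(profile.distinct, small_config.hash_bits)).size
    assert catalog.ref_count(g.strain_taxid) == n_addr
    counts = matrix.state_counts(catalog)
    assert counts["strain"] == n_addr and counts["black"] == 0 and counts["genus"] == 0


def test_build_two_same_genus_strains_identical_genomes(tmp_path, small_config):
    clade, tree = toy_tree(tmp_path, n_genera=1, strains_per_species=2)
    g1, g2 = clade.genomes
    shared = profile_of(g1.sequence, small_config)
    table = {
        g1.strain_taxid: [(g1.accession, shared)],
        g2.strain_taxid: [(g2.accession, shared)],
    }
    matrix, catalog = mt.build_reference(table, tree, small_config)
    counts = matrix.state_counts(catalog)
    assert counts["strain"] == 0 and counts["black"] == 0
    assert counts["genus"] > 0
    assert catalog.ref_count(g1.strain_taxid) == 0
    assert catalog.ref_count(g2.strain_taxid) == 0


def test_build_two_genera_identical_genomes_black(tmp_path, small_config):
    clade, tree = toy_tree(tmp_path, n_genera=2, strains_per_species=1)
    g1, g2 = clade.genomes
    shared = profile_of(g1.sequence, small_config)
    table = {
        g1.strain_taxid: [(g1.accession, shared)],
        g2.strain_taxid: [(g2.accession, shared)],
    }
    matrix, catalog = mt.build_reference(table, tree, small_config)
    counts = matrix.state_counts(catalog)
    assert counts["strain"] == 0 and counts["genus"] == 0
    assert counts["black"] > 0


def test_build_conservation_and_refcount_consistency(built_reference):
    matrix, catalog = built_reference
    counts = matrix.state_counts(catalog)
    assert sum(counts.values()) == matrix.n_slots
    assert sum(info.ref_count for info in catalog.strains.values()) == counts["strain"]


def test_build_order_invariance(tmp_path, small_config):
    clade, tree = toy_tree(tmp_path, n_genera=2, strains_per_species=2)
    table = strain_table_of(clade, small_config)
    reference = None
    for order in itertools.permutations(table):
        permuted = {k: table[k] for k in order}
        matrix, _ = mt.build_reference(permuted, tree, small_config)
        if reference is None:
            reference = matrix.slots
        else:
            assert np.array_equal(matrix.slots, reference)


def test_non_representative_genomes_do_not_change_matrix(tmp_path, small_config):
    clade, tree = toy_tree(tmp_path, n_genera=2, strains_per_species=1)
    g1, g2 = clade.genomes
    p1 = profile_of(g1.sequence, small_config)
    table_single = {
        g1.strain_taxid: [(g1.accession, p1)],
        g2.strain_taxid: [(g2.accession, profile_of(g2.sequence, small_config))],
    }
    # add a second genome to strain 1 with a *larger* minimizer set; the
    # single original remains nearest the median and stays representative
    bigger = profile_of(g1.sequence + g2.sequence, small_config)
    table_multi = {
        g1.strain_taxid: [(g1.accession, p1), (g1.accession + "_alt", bigger)],
        g2.strain_taxid: table_single[g2.strain_taxid],
    }
    m1, _ = mt.build_reference(table_single, tree, small_config)
    m2, _ = mt.build_reference(table_multi, tree, small_config)
    assert np.array_equal(m1.slots, m2.slots)


@pytest.fixture
def flat_tree(tmp_path):
    from test_taxonomy import write_dumps

    nodes, names = write_dumps(
        tmp_path,
        [(1, 1, "no rank"), (50, 1, "species"), (51, 50, "strain")],
        [(1, "root", "", "scientific name")],
    )
    return mt.load_taxonomy(nodes, names)


def test_operative_genus_fallback_in_build(flat_tree, small_config):
    """A strain with no genus rank builds under its operative genus; with no
    usable rank at all the build errors naming the accession."""
    profile = profile_of(mt.simulate_genome(1_000, 0.5, 2), small_config)
    with pytest.raises(ValueError, match="ACCX"):
        mt.build_reference({51: [("ACCX", profile)]}, flat_tree, small_config)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def test_serialize_roundtrip(tmp_path, built_reference):
    matrix, catalog = built_reference
    path = tmp_path / "ref.bin"
    mt.serialize_reference(matrix, catalog, path)
    loaded_matrix, loaded_catalog = mt.load_reference(path)
    assert np.array_equal(loaded_matrix.slots, matrix.slots)
    assert loaded_matrix.hash_bits == matrix.hash_bits
    assert loaded_catalog == catalog


def test_serialized_size_matches_layout(tmp_path, small_config):
    matrix = mt.StorageMatrix.zeros(small_config.hash_bits)
    catalog = mt.RefCatalog(config=small_config)
    path = tmp_path / "ref.bin"
    mt.serialize_reference(matrix, catalog, path)
    size = path.stat().st_size
    header = 8 + 5  # magic + (version, k, n, h)
    assert size >= header + 4 * 2**small_config.hash_bits + 8
    # slots block is exactly 4 * 2^h of the total
    blob = size - header - 4 * 2**small_config.hash_bits - 8
    assert blob > 0  # the JSON catalogue block


def test_load_rejects_corrupt_files(tmp_path, built_reference):
    matrix, catalog = built_reference
    good = tmp_path / "ref.bin"
    mt.serialize_reference(matrix, catalog, good)
    bad_magic = tmp_path / "bad.bin"
    bad_magic.write_bytes(b"NOTAREF!" + good.read_bytes()[8:])
    with pytest.raises(ReferenceFormatError, match="magic"):
        mt.load_reference(bad_magic)
    truncated = tmp_path / "trunc.bin"
    truncated.write_bytes(good.read_bytes()[: 8 + 5 + 100])
    with pytest.raises(ReferenceFormatError, match="truncated"):
        mt.load_reference(truncated)
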