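import collections

import pytest

import minitax as mt


@pytest.fixture(scope="session")
def small_config() -> mt.KmerConfig:
    """Short windows and a folded hash space so matrices stay tiny."""
    return mt.KmerConfig(k=9, n=5, hash_bits=16)


@pytest.fixture(scope="session")
def clade():
    """Seeded 3x2x2 clade, 20 kb genomes, written to a session tmp dir."""
    spec = mt.FixtureSpec(
        n_genera=3,
        species_per_genus=2,
        strains_per_species=2,
        genome_length=20_000,
        seed=11,
    )
    return mt.make_clade(spec)


@pytest.fixture(scope="session")
def clade_on_disk(tmp_path_factory):
    spec = mt.FixtureSpec(genome_length=20_000, seed=11)
    return mt.make_clade(spec, out_dir=tmp_path_factory.mktemp("clade"))


@pytest.fixture(scope="session")
def clade_tree(clade_on_disk):
    return mt.load_taxonomy(clade_on_disk.nodes_dump, clade_on_disk.names_dump)


def strain_table_of(clade, config):
    table = collections.defaultdict(list)
    for g in clade.genomes:
        table[g.strain_taxid].append(
            (g.accession, mt.profile_genome([g.sequence], config))
        )
    return dict(table)


@pytest.fixture(scope="session")
def reference_config() -> mt.KmerConfig:
    return mt.KmerConfig(k=61, n=31, hash_bits=20)


@pytest.fixture(scope="session")
def built_reference(clade, clade_tree, reference_config):
    """Matrix + catalog over the session clade."""
    table = strain_table_of(clade, reference_config)
    matrix, catalog = mt.build_reference(table, clade_tree, reference_config)
    return matrix, catalog
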