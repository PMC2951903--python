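import numpy as np
import pytest

from lecatrace.fixtures import load_fixture
from lecatrace.matrix import PresenceMatrix, TaxonEntry, TaxonomyMap


@pytest.fixture(scope="session")
def nup_matrix():
    return load_fixture("nup_table2")


@pytest.fixture(scope="session")
def nup_taxonomy():
    return load_fixture("taxonomy_table2")


@pytest.fixture(scope="session")
def coatomer_matrix():
    return load_fixture("coatomer_table5")


@pytest.fixture(scope="session")
def coatomer_taxonomy():
    return load_fixture("taxonomy_table5")


@pytest.fixture(scope="session")
def fungi_matrix():
    return load_fixture("fungi_table4")


@pytest.fixture(scope="session")
def fungi_taxonomy():
    return load_fixture("taxonomy_table4")


@pytest.fixture(scope="session")
def mitosis_phenotypes():
    return load_fixture("mitosis_phenotypes")


@pytest.fixture(scope="session")
def control_reference():
    return load_fixture("tbrucei_table1")


def random_matrix_and_taxonomy(rng, n_components=8, n_genomes=10, n_supergroups=4):
    """Small random presence matrix with a matching taxonomy."""
    supergroups = tuple(f"SG{k}" for k in range(n_supergroups))
    genomes = tuple(f"g{j}" for j in range(n_genomes))
    states = (rng.random((n_components, n_genomes)) < 0.5).astype(np.int8)
    matrix = PresenceMatrix(
        components=tuple(f"c{i}" for i in range(n_components)),
        genomes=genomes,
        states=states,
    )
    entries = {
        g: TaxonEntry(species="", clade_class="", supergroup=supergroups[j % n_supergroups])
        for j, g in enumerate(genomes)
    }
    taxonomy = TaxonomyMap(entries=entries, supergroups=supergroups)
    return matrix, taxonomy
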