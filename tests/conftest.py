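import pytest

from biokr import load_example_kb, load_upper_ontology


@pytest.fixture(scope="session")
def upper_kb():
    return load_upper_ontology()


@pytest.fixture(scope="session")
def cell_kb():
    return load_example_kb("cell-a1-a4")


@pytest.fixture(scope="session")
def biomembrane_kb():
    return load_example_kb("biomembrane")


@pytest.fixture(scope="session")
def plant_kb():
    return load_example_kb("plant-cell")


@pytest.fixture(scope="session")
def dna_kb():
    return load_example_kb("dna-gene")
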