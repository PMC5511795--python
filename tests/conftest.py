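import pytest

from oncopanel import load_default_panel, make_reference


@pytest.fixture(scope="session")
def registry():
    return load_default_panel()


@pytest.fixture(scope="session")
def small_reference():
    """Four genes, two 300-bp exons each."""
    return make_reference(n_genes=4, exons_per_gene=2, exon_len=300, seed=11)


@pytest.fixture(scope="session")
def homolog_reference():
    """Reference carrying an identical dead-zone pair and a low-stringency
    homolog pair."""
    return make_reference(n_genes=2, exons_per_gene=1, exon_len=300,
                          homolog_pair=True, seed=7)
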