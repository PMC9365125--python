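import pytest

from genotax import make_pair, make_panel
from genotax.genome_io import extract_proteome
from genotax.pangenome import cluster_proteins


@pytest.fixture(scope="session")
def small_pair():
    """200 kb ancestor/descendant pair at d = 0.05 with a full proteome."""
    return make_pair(seed=1, divergence=0.05, length=200_000)


@pytest.fixture(scope="session")
def two_clade_panel():
    """Eight-genome two-clade panel (bundled strain gene patterns)."""
    genomes, panel = make_panel(seed=42)
    return genomes, panel


@pytest.fixture(scope="session")
def panel_clusters(two_clade_panel):
    genomes, panel = two_clade_panel
    proteomes = {g.genome_id: extract_proteome(g) for g in genomes}
    return cluster_proteins(proteomes)
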