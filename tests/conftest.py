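import warnings

import pytest

from mitocode import (SimulationConfig, annotate_by_homology, detect_split_genes,
                      simulate_panel, simulate_query_genome, table4)

warnings.filterwarnings("ignore", message=".*gap_score.*")


@pytest.fixture(scope="session")
def default_cfg():
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def panel(default_cfg):
    return simulate_panel(default_cfg)


@pytest.fixture(scope="session")
def panel_proteins(panel):
    return panel.proteins_by_gene()


@pytest.fixture(scope="session")
def genome(default_cfg, panel):
    """(contigs, truth) for the default study conditions, seed 1."""
    return simulate_query_genome(default_cfg, panel)


@pytest.fixture(scope="session")
def mito_contig(genome):
    return genome[0][0]


@pytest.fixture(scope="session")
def truth(genome):
    return genome[1]


@pytest.fixture(scope="session")
def annotations(mito_contig, panel_proteins):
    anns = annotate_by_homology(mito_contig, panel_proteins, table4())
    return detect_split_genes(anns)
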