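import numpy as np
import pytest

from arrestscan.genome import GeneRecord, Genome
from arrestscan.synthetic import PanelConfig, generate_panel


@pytest.fixture(scope="session")
def default_panel():
    """One noiseless 10-species panel shared by the slower integration tests."""
    return generate_panel(PanelConfig(seed=11))


@pytest.fixture(scope="session")
def screened_panel(default_panel):
    from arrestscan.screen import run_screen

    genomes, manifest = default_panel
    return genomes, manifest, run_screen(genomes)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_genome(seq: str, genes=None, genome_id: str = "G1") -> Genome:
    return Genome(genome_id=genome_id, sequence=seq, genes=list(genes or []))


def make_gene(start, end, strand="+", name="", product="", gene_id="g1"):
    keywords = tuple(product.lower().split()) if product else ()
    return GeneRecord(
        gene_id=gene_id, start=start, end=end, strand=strand,
        name=name, product_keywords=keywords,
    )
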