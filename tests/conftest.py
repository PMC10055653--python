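import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from pauseatlas import synthetic_data as sd


@pytest.fixture(scope="session")
def small_species():
    """A 60-gene synthetic species with tracks at moderate depth."""
    genome, genes, truths = sd.generate_genome_with_genes(
        60, gene_length=2000, seed=11, pausing_index=10.0, motif="CGCCGCC",
        motif_fraction=0.5,
    )
    five, three = sd.simulate_proseq_tracks(genes, truths, total_reads=120_000, seed=12)
    return genome, genes, truths, five, three


@pytest.fixture(scope="session")
def proteome_fixture():
    """The 6-family x 5-species proteome set with known ortholog truth."""
    specs = sd.example_proteome_specs()
    query, proteomes, truth = sd.generate_proteome_set(6, specs, seed=7)
    return query, proteomes, truth, specs
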