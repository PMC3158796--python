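import hypothesis
import numpy as np
import pytest

from metacomp import synthetic_data as syn
from metacomp.sequence_io import Read, ReadSet

hypothesis.settings.register_profile(
    "metacomp", deadline=None, derandomize=True, max_examples=50)
hypothesis.settings.load_profile("metacomp")


@pytest.fixture(scope="session")
def genome_50pct():
    """A 100 kb i.i.d. genome at 50% GC."""
    return syn.simulate_genome(100_000, 0.5, seed=1, genome_id="g50")


@pytest.fixture(scope="session")
def three_genome_community():
    """3000 reads from three genomes at abundances 0.6/0.3/0.1, 1.5% error."""
    genomes = [
        syn.simulate_genome(30_000, 0.45, seed=101, genome_id="gA", taxon_label="Actinobacteria"),
        syn.simulate_genome(30_000, 0.55, seed=102, genome_id="gB", taxon_label="Betaproteobacteria"),
        syn.simulate_genome(30_000, 0.65, seed=103, genome_id="gC", taxon_label="Crenarchaeota"),
    ]
    reads, truth = syn.simulate_community(
        genomes, [0.6, 0.3, 0.1], n_reads=3000, error_rate=0.015, seed=104,
        label="community3")
    return genomes, reads, truth


def make_reads(label, sequences):
    return ReadSet(label, [Read(f"{label}_r{i}", s) for i, s in enumerate(sequences)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
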