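import pytest

from splicem6a.simulate import SyntheticConfig, build_toy_genome


@pytest.fixture(scope="session")
def toy_config():
    return SyntheticConfig(seed=42, n_genes=50, n_planted_structured=3,
                           n_planted_unstructured=3)


@pytest.fixture(scope="session")
def toy_dataset(toy_config):
    """Seeded toy genome + annotation + truth manifest shared across tests."""
    genome, transcripts, manifest = build_toy_genome(toy_config)
    return genome, transcripts, manifest
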