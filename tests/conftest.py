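import numpy as np
import pytest

from mirseeds import (
    ConservationTrack,
    DiscoveryConfig,
    GeneRecord,
    GenomeAssembly,
    SimConfig,
    simulate_bundle,
)


@pytest.fixture()
def flat_genome():
    """A 1 kb single-chromosome genome with a repeating ACGT pattern."""
    return GenomeAssembly("spX", {"chr1": "ACGT" * 250})


@pytest.fixture()
def full_track():
    """Conservation track fully covered with score 0.5."""
    return ConservationTrack({"chr1": np.full(1000, 0.5)})


@pytest.fixture()
def plus_gene():
    return GeneRecord("gA", "chr1", 100, 500, "+")


@pytest.fixture(scope="session")
def small_sim():
    """A small planted bundle with a strong effect, shared by slower
    integration tests."""
    config = SimConfig(seed=11, n_species=3, n_genes=40, chrom_length=25_000,
                       plant_prob=0.5)
    bundles, truth = simulate_bundle(config)
    return config, bundles, truth


@pytest.fixture(scope="session")
def default_discovery_config():
    return DiscoveryConfig()
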