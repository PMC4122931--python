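import pytest

from endoerode.synthetic import (
    MatePairConfig,
    SimulationConfig,
    generate_genome,
    plant_repeats,
    scaffoldize,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=11,
        genome_length=100_000,
        n_genes=60,
        n_gaps=6,
        matepair=MatePairConfig(n_pairs=5_000),
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    """(scaffolds, features) of one clean synthetic chromosome."""
    return generate_genome(small_config)[:2]


@pytest.fixture(scope="session")
def gapped_scaffolds(small_config, small_genome):
    """Scaffolds with N-gaps and planted repeats plus both truth sets."""
    genome, features = small_genome
    scaffolds, gap_truth = scaffoldize(
        genome, features, small_config.n_gaps, small_config.gap_size_range,
        small_config.seed,
    )
    scaffolds, repeat_truth = plant_repeats(
        scaffolds, features, small_config.n_repeat_families,
        small_config.repeat_copies, small_config.repeat_length, small_config.seed,
    )
    return scaffolds, features, gap_truth, repeat_truth
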