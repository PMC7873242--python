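"""Shared fixtures: small simulated scenarios built at test time."""

import pytest

from l1m6a.simulate import SimConfig, build_consensus_lineage, simulate_genomes


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale scenario: 3 species, 80 kb ancestor, 700 bp consensus."""
    return SimConfig(
        seed=7, n_species=3, ancestral_genome_len=80_000,
        consensus_len=700, utr_span=(1, 650),
        n_shared_insertions=3, n_specific_insertions_per_species=4,
        truncation_min_cut=150, truncation_prob=0.25,
        anchor_min_separation=4500, edge_margin=3000,
    )


@pytest.fixture(scope="session")
def small_library(small_config):
    return build_consensus_lineage(small_config)


@pytest.fixture(scope="session")
def small_sim(small_config, small_library):
    return simulate_genomes(small_config, small_library)


@pytest.fixture(scope="session")
def full_scale_library():
    """Full-length (6019 bp) consensus lineage for realistic-scale tests."""
    return build_consensus_lineage(SimConfig(seed=3, ancestral_genome_len=100_000,
                                             n_shared_insertions=0,
                                             n_specific_insertions_per_species=0))
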