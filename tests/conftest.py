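"""Shared fixtures: small simulated communities reused across test modules."""

import numpy as np
import pytest

from strainsites import SimulationConfig, simulate_community


@pytest.fixture(scope="session")
def skewed_community():
    """A 200 kb genome with default skew/PTR structure and a 2-sample pileup."""
    cfg = SimulationConfig(
        genome_length=200_000,
        skew_amplitude=0.1,
        true_ptr=2.0,
        mean_coverage=50.0,
        n_samples=2,
        haplotypes=[{}, {10_000: "G", 50_000: "T", 120_000: "C"}],
        haplotype_frequencies=[[0.7, 0.3], [0.4, 0.6]],
        seed=11,
    )
    return simulate_community(cfg)


@pytest.fixture(scope="session")
def flat_community():
    """Non-replicating population: uniform expected coverage, no variants."""
    cfg = SimulationConfig(genome_length=100_000, true_ptr=1.0, mean_coverage=50.0,
                           n_samples=1, seed=5)
    return simulate_community(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
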