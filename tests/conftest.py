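import numpy as np
import pytest

from yeastpop.simulate import (
    SimulationConfig,
    simulate_coverage,
    simulate_facs,
    simulate_population,
)


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition population (n=50, full 16-chromosome genome),
    shared across tests that exercise the study-scale conditions."""
    config = SimulationConfig(seed=1)
    genotypes, truth = simulate_population(config)
    return config, genotypes, truth


@pytest.fixture(scope="session")
def default_sim_with_coverage(default_sim):
    config, genotypes, truth = default_sim
    coverage, allele_depths = simulate_coverage(genotypes, truth, config)
    facs = simulate_facs(truth, config)
    return config, genotypes, truth, coverage, allele_depths, facs


@pytest.fixture(scope="session")
def small_config():
    """A reduced genome for fast I/O round-trips."""
    return SimulationConfig(
        seed=3, n_isolates=6, chromosome_lengths=(150_000, 120_000), het_rate=2.0
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
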