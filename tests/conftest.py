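import numpy as np
import pytest

from somaclock.synthetic import SimConfig, simulate_genome


@pytest.fixture(scope="session")
def syn_genome():
    """Shared 400 kb synthetic genome with annotation tracks."""
    return simulate_genome(SimConfig(seed=42, genome_length=400_000))


@pytest.fixture(scope="session")
def genome(syn_genome):
    return syn_genome.genome


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def small_config(**kwargs) -> SimConfig:
    """Fast lineage-simulation config for unit tests."""
    defaults = dict(
        seed=7,
        genome_length=400_000,
        cells_per_subject=16,
        subject_ages=(60.0,),
        division_schedule=((0.05, 2), (0.2, 2)),
        terminal_times=0.4,
        clonal_mu=20.0,
        clonal_indel_mu=2.0,
        aging_rate=8.0,
        aging_intercept=20.0,
        aging_indel_rate=0.5,
        aging_indel_intercept=3.0,
        detect_sensitivity={"30X": 1.0},
        callable_fraction={"30X": 1.0},
    )
    defaults.update(kwargs)
    return SimConfig(**defaults)
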