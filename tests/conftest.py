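"""Shared fixtures: simulated cohorts reused across the test modules."""

import numpy as np
import pytest

from nuptools.discovery import (
    assemble_nupt_set,
    dedupe_hits,
    filter_distance,
    filter_length,
    naive_local_align,
)
from nuptools.synthetic import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_cohort():
    """A full default-condition dataset (300 insertions) plus its discovered
    NUPT set — the main study-scale fixture."""
    result = simulate_dataset(SimulationConfig(seed=11))
    hits = naive_local_align(result.plastid, result.genome)
    filter_length(hits)
    filter_distance(hits)
    dedupe_hits(hits)
    records = assemble_nupt_set(hits)
    return result, records


@pytest.fixture(scope="session")
def small_sim():
    """A small, fast dataset for plumbing tests."""
    config = SimulationConfig(
        seed=5,
        n_insertions=30,
        n_chromosomes=1,
        chromosome_lengths=(120_000,),
        plastid_length=40_000,
    )
    return simulate_dataset(config)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
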