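"""Shared fixtures: small simulated genomes and a tumor scenario.

Session-scoped so the expensive simulations run once per test session.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from rmapforge.core_maps import GenomeMaps
from rmapforge.simulate import (
    SimulationConfig,
    implant_variants,
    place_default_truth_set,
    simulate_reference,
    simulate_rmaps,
)


@pytest.fixture(scope="session")
def small_genome():
    """3 Mb single-chromosome genome with human-like GC."""
    sequences, genome = simulate_reference({"chr1": 3_000_000}, seed=1)
    return sequences, genome


@pytest.fixture(scope="session")
def two_chrom_genome():
    """10 Mb genome as two 5 Mb chromosomes."""
    sequences, genome = simulate_reference(
        {"chr1": 5_000_000, "chr2": 5_000_000}, seed=1
    )
    return sequences, genome


@pytest.fixture(scope="session")
def tumor_scenario(two_chrom_genome):
    """Reference + tumor genome with the standard five-variant truth set."""
    sequences, genome = two_chrom_genome
    rng = np.random.default_rng(42)
    specs = place_default_truth_set(sequences, genome, rng)
    tumor_seqs, truth = implant_variants(sequences, specs, seed=2)
    tumor_genome = GenomeMaps.from_sequences(tumor_seqs)
    return {
        "reference": genome,
        "sequences": sequences,
        "tumor_genome": tumor_genome,
        "tumor_sequences": tumor_seqs,
        "truth": truth,
        "specs": specs,
    }


@pytest.fixture(scope="session")
def noisy_rmaps(two_chrom_genome):
    """Default-noise molecules from the unaltered 10 Mb genome at 15x."""
    _, genome = two_chrom_genome
    cfg = SimulationConfig(seed=3, coverage=15)
    return simulate_rmaps({"s1": genome}, cfg)


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield
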