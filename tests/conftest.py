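"""Shared fixtures: small simulated worlds reused across test modules."""

from __future__ import annotations

import pytest

from damidseq import genomap, simdata


SMALL = simdata.SimConfig(
    seed=11,
    n_chrom=2,
    chrom_lengths=(40_000, 30_000),
    gatc_spacing_mean=150.0,
    n_genes=12,
    gene_length_range=(800, 1500),
    n_targets=3,
    n_reads_per_sample=8_000,
)


@pytest.fixture(scope="session")
def small_config() -> simdata.SimConfig:
    return SMALL


@pytest.fixture(scope="session")
def small_world(small_config) -> simdata.SimulatedWorld:
    """One fully simulated small world shared (read-only) by many tests."""
    return simdata.simulate_world(small_config)


@pytest.fixture(scope="session")
def small_index(small_world) -> genomap.GatcIndex:
    return genomap.GatcIndex.build(small_world.genome, small_world.gatc_map)
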