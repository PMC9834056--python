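"""Shared fixtures: tiny literal genomes and small simulated datasets."""

import numpy as np
import pytest

from svfootprint.io import Genome
from svfootprint.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def toy_genome() -> Genome:
    """Two fixed 60-bp contigs for hand-checkable flank extraction."""
    rng = np.random.default_rng(1234)
    bases = "ACGT"
    contigs = {
        name: "".join(bases[i] for i in rng.integers(0, 4, size=60))
        for name in ("tigA", "tigB")
    }
    return Genome(contigs)


@pytest.fixture(scope="session")
def small_dataset():
    """A small full simulation shared across tests (read-only)."""
    config = SimulationConfig(
        seed=42,
        contig_lengths={"chrI": 150_000, "chrII": 100_000},
        n_translocations=80,
        n_deletions=80,
        n_inherited_background_svs=12,
        ci_width=0,
    )
    return simulate(config)
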