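import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from nucleoidmc.chain import (
    ChainPlacement,
    ChainSpec,
    Structure,
    Topology,
    discretize_chromosome,
)


def ring_structure(n_segments: int, diameter: float = 35.0) -> Structure:
    """A single circular chain with the standard discretization."""
    genome = int(round(n_segments * 10_000 / 3))
    spec = discretize_chromosome(
        ChainSpec(genome_length_bp=genome, hard_core_diameter_nm=diameter)
    )
    assert spec.n_segments == n_segments
    return Structure(Topology([ChainPlacement(spec, "chr")]))


def linear_structure(n_segments: int, diameter: float = 35.0) -> Structure:
    genome = int(round(n_segments * 10_000 / 3))
    spec = discretize_chromosome(
        ChainSpec(
            genome_length_bp=genome, hard_core_diameter_nm=diameter, circular=False
        )
    )
    return Structure(Topology([ChainPlacement(spec, "chr")]))


@pytest.fixture
def rng():
    return np.random.default_rng(20250927)
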