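"""Shared fixtures: small synthetic genomes and simulated contact matrices."""

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from proxiscaf import (
    Bin,
    GenomeStructure,
    NuisanceParams,
    SimulationSpec,
    simulate_contacts,
    yeast_like_genome,
)

PARAMS = NuisanceParams(b=-1.5, s0=1.0e5, pt=1.0e-9)


@pytest.fixture
def toy_bins():
    """Six orientable 10-kb bins."""
    return [Bin(i, 10_000, 4, source_name="chr1", source_start=i * 10_000) for i in range(6)]


@pytest.fixture
def toy_structure(toy_bins):
    """Two scaffolds: [0,1,2] and [3,4,5], all forward."""
    return GenomeStructure.from_arrangement(
        toy_bins, [[(0, 1), (1, 1), (2, 1)], [(3, 1), (4, 1), (5, 1)]]
    )


@pytest.fixture(scope="session")
def small_genome():
    """16-chromosome yeast-ratio genome scaled to 30 bins."""
    return yeast_like_genome(total_bp=900_000, n_bins=30)


@pytest.fixture(scope="session")
def small_data(small_genome):
    return simulate_contacts(SimulationSpec(small_genome, PARAMS, 500_000, seed=11))


@pytest.fixture(scope="session")
def medium_genome():
    return yeast_like_genome(total_bp=1_500_000, n_bins=50)


@pytest.fixture(scope="session")
def medium_data(medium_genome):
    return simulate_contacts(SimulationSpec(medium_genome, PARAMS, 1_000_000, seed=7))


def random_placed_pair(structure, rng):
    """Two distinct placements drawn uniformly from a structure."""
    placed = [
        (p.bin_id, p.copy_index) for sc in structure.scaffolds for p in sc.placed
    ]
    a = placed[rng.integers(len(placed))]
    b = placed[rng.integers(len(placed))]
    while b == a:
        b = placed[rng.integers(len(placed))]
    return a, b
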