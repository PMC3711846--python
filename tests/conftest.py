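import numpy as np
import pytest

from chipdomains import (
    GenomeModel,
    GenomicRegion,
    SimulationTruth,
    plant_domains,
    simulate_tags,
)


@pytest.fixture(scope="session")
def genome2mb() -> GenomeModel:
    return GenomeModel(("chr1",), (2_000_000,))


@pytest.fixture(scope="session")
def genome_multi() -> GenomeModel:
    return GenomeModel(("chr1", "chr2"), (1_200_000, 800_000))


@pytest.fixture(scope="session")
def planted_truth(genome2mb) -> SimulationTruth:
    """20 domains of 5-50 kb at fold 5, matched 1e5-tag libraries."""
    domains = plant_domains(genome2mb, 20, (5_000, 50_000), seed=1)
    return SimulationTruth(
        genome=genome2mb,
        domains=domains,
        fold=5.0,
        n_chip=100_000,
        n_input=100_000,
        seed=42,
    )


@pytest.fixture(scope="session")
def simulated_pair(planted_truth):
    return simulate_tags(planted_truth)


def region_bp(regions) -> int:
    return sum(r.length for r in regions)


def intersection_bp(a: list, b: list) -> int:
    """Brute-force total intersection between two region lists (bp)."""
    total = 0
    for ra in a:
        for rb in b:
            if ra.chrom != rb.chrom:
                continue
            total += max(0, min(ra.end, rb.end) - max(ra.start, rb.start))
    return total
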