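from __future__ import annotations

import numpy as np
import pytest

from xenoscan import simulate as sim

SITE = "TCGATAAATT"
SITE_VARIANT = "TCGAATAATT"


def random_dna(rng: np.random.Generator, n: int, gc: float = 50.0) -> str:
    g = gc / 200.0
    a = (100.0 - gc) / 200.0
    return "".join(rng.choice(list("ACGT"), size=n, p=[a, g, g, a]))


@pytest.fixture(scope="session")
def planted_genome():
    """50 kb, 60% GC genome with one AT island, 20 planted sites, operon layout."""
    spec = sim.SyntheticGenomeSpec(
        length=50_000,
        gc=60.0,
        islands=(sim.IslandSpec(10_000, 2_000, 40.0),),
        sites=tuple(sim.PlantedSite(p, SITE) for p in range(30_000, 32_000, 100)),
        genes=sim.GeneLayoutSpec(),
        seed=11,
    )
    return sim.simulate_genome(spec)


@pytest.fixture(scope="session")
def two_variant_genome():
    """Genome planting 10 copies each of two site variants differing at the core.

    10 kb background so the 20 planted occurrences dominate the first-pass
    PFM over chance near-miss windows — the constructed minimal case for
    consensus refinement.
    """
    sites = tuple(
        sim.PlantedSite(p, SITE if i % 2 == 0 else SITE_VARIANT)
        for i, p in enumerate(range(4_000, 6_000, 100))
    )
    spec = sim.SyntheticGenomeSpec(length=10_000, gc=60.0, sites=sites, seed=13)
    return sim.simulate_genome(spec)


@pytest.fixture(scope="session")
def contig_set():
    return sim.simulate_contig_set(k=3, contigs_per_group=5, length=6_000, seed=17)


@pytest.fixture(scope="session")
def genotype_pair(planted_genome):
    genome, genes, _ = planted_genome
    return sim.simulate_genotype_pair(
        genome, genes, n_syn=20, n_nonsyn=5, n_intergenic=10, seed=19
    )
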