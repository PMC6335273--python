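import numpy as np
import pytest

from passcan.synthetic import SimConfig, SimWorld, simulate_world
from passcan.variants import GenotypeSite, PopulationSpec


@pytest.fixture(scope="session")
def default_world() -> SimWorld:
    """One default-scale synthetic world, shared across the session."""
    return simulate_world(SimConfig(seed=1))


@pytest.fixture(scope="session")
def small_world() -> SimWorld:
    """A reduced world for cheap end-to-end exercises."""
    return simulate_world(SimConfig(seed=7, n_chroms=1, chrom_length=800_000,
                                    n_genes=40, n_qtls=3))


@pytest.fixture
def spec() -> PopulationSpec:
    return PopulationSpec(
        "A", "B",
        tuple(f"A{i}" for i in range(1, 13)),
        tuple(f"B{i}" for i in range(1, 12)),
        min_called_a=10, min_called_b=9)


def make_site(spec: PopulationSpec, gts_a, gts_b, chrom="chr1", pos=100,
              ref="A", alts=("T",)) -> GenotypeSite:
    """Build a site from per-population genotype tuples (padded with 0/0)."""
    genotypes = {}
    for i, sample in enumerate(spec.samples_a):
        genotypes[sample] = gts_a[i] if i < len(gts_a) else (0, 0)
    for i, sample in enumerate(spec.samples_b):
        genotypes[sample] = gts_b[i] if i < len(gts_b) else (0, 0)
    return GenotypeSite(chrom, pos, ref, tuple(alts), genotypes)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
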