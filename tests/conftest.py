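"""Shared synthetic fixtures.

The "small world" is one modest diploid genome (200 kb haploid) carried
through assembly, read simulation, and best-4 mapping once per session; the
mapping-heavy tests share it to keep the suite fast.
"""

import numpy as np
import pytest

from haplodiag.mapping import KmerIndex, MapperConfig, map_pairs
from haplodiag.simulate import (
    GenomeSimSpec,
    ReadSimSpec,
    simulate_assembly,
    simulate_diploid_genome,
    simulate_reads,
)


@pytest.fixture(scope="session")
def small_world():
    gspec = GenomeSimSpec(seed=11, chrom_length=200_000, gene_count=20, gene_loss_rate=0.1)
    genome = simulate_diploid_genome(gspec)
    assembly = simulate_assembly(genome)
    reads = simulate_reads(genome, ReadSimSpec(seed=12, depth_total=36, error_rate=0.005))
    index = KmerIndex(assembly.contigs, 13)
    best4 = map_pairs(reads, index, MapperConfig.best4(seed=1))
    return {
        "genome": genome,
        "assembly": assembly,
        "reads": reads,
        "index": index,
        "best4": best4,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
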