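import numpy as np
import pandas as pd
import pytest

from ssi_cistrome.core import GeneModel, GenomeIndex, Interval, Transcriptome
from ssi_cistrome.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down study: fast enough for per-test use, same structure."""
    return SimulationConfig(
        n_chroms=2, chrom_bp=150_000, n_genes=10, n_true_sites=30,
        n_artifact_sites=4, depth_per_replicate=15_000, secondary_depth=15_000,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture
def genome():
    return GenomeIndex({"chr1": 100_000, "chr2": 50_000})


@pytest.fixture
def toy_transcriptome():
    """Two hand-built genes with known structure on a 100 kb chromosome.

    geneA (+): tx 20000-26000, exons [20000,21000), [22000,23000),
    [25000,26000); CDS 20500-25500. TSS 20000.
    geneB (-): tx 60000-66000, exons [60000,61500), [63000,66000);
    CDS 60400-65600. TSS 65999.
    """
    chrom = "chr1"
    gene_a = GeneModel(
        gene_symbol="geneA", transcript_id="txA", chrom=chrom, strand="+",
        tx_start=20_000, tx_end=26_000,
        exons=[Interval(chrom, 20_000, 21_000), Interval(chrom, 22_000, 23_000),
               Interval(chrom, 25_000, 26_000)],
        cds_start=20_500, cds_end=25_500,
    )
    gene_b = GeneModel(
        gene_symbol="geneB", transcript_id="txB", chrom=chrom, strand="-",
        tx_start=60_000, tx_end=66_000,
        exons=[Interval(chrom, 60_000, 61_500), Interval(chrom, 63_000, 66_000)],
        cds_start=60_400, cds_end=65_600,
    )
    return Transcriptome([gene_a, gene_b], GenomeIndex({chrom: 100_000}))


def random_tag_frame(rng, n, chroms=("chr1",), max_pos=100_000):
    from ssi_cistrome.core import make_tags
    return make_tags(
        rng.choice(chroms, size=n),
        rng.integers(0, max_pos, size=n),
        rng.choice(["+", "-"], size=n),
    )
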