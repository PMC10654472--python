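import numpy as np
import pandas as pd
import pytest

from domescan import synthetic_data as sd
from domescan.gene_level import GENOTYPE_COLUMNS


def make_genotype_table(rows):
    """Build a genotype table from (individual, pop, origin, period, locus, a1, a2) rows."""
    return pd.DataFrame(rows, columns=GENOTYPE_COLUMNS)


@pytest.fixture(scope="session")
def small_poolseq_sim():
    """A small seeded Pool-Seq simulation shared across read-only tests."""
    cfg = sd.PoolSeqSimConfig(
        chrom_length=2_000_000,
        n_snps=2_000,
        mean_depth=60.0,
        selected_region=(900_000, 1_100_000, 0.3),
        seed=11,
    )
    return sd.generate_poolseq(cfg)


@pytest.fixture(scope="session")
def null_gene_table():
    """Gene-level table with no origin effect (farmed frequency fixed to wild's)."""
    return sd.generate_gene_level(
        sd.GeneLevelSimConfig(wild_allele_freq=0.5, farmed_allele_freq=0.5, seed=101)
    )
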