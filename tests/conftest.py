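import numpy as np
import pandas as pd
import pytest

from dmrkit.io import CYTOSINE_COLUMNS, MethylomeTable
from dmrkit.simulate import SimConfig, generate_genome_annotation, generate_true_methylome


def make_table(rows, sample_id="s", genome_id="genome"):
    """rows: (chrom, pos0, strand, count_m, count_u, context)."""
    df = pd.DataFrame(rows, columns=CYTOSINE_COLUMNS)
    return MethylomeTable(sample_id=sample_id, df=df, genome_id=genome_id)


def random_table(rng, n_sites=500, chrom_span=10_000, contexts=("CG", "CHG", "CHH"), sample_id="r", chrom="Chr1"):
    pos = np.sort(rng.choice(chrom_span, size=n_sites * 2, replace=False))[:n_sites]
    strand = rng.choice(["+", "-"], size=n_sites)
    cov = rng.poisson(12, size=n_sites)
    m = rng.binomial(cov, rng.uniform(0, 1, size=n_sites))
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "strand": strand,
            "count_m": m,
            "count_u": cov - m,
            # context is a property of the genomic position, so derive it
            # deterministically to keep independently drawn tables consistent
            "context": [contexts[p % len(contexts)] for p in pos],
        }
    )
    return MethylomeTable(sample_id=sample_id, df=df, genome_id="genome")


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(chrom_length=200_000, seed=42)


@pytest.fixture(scope="session")
def small_genome(small_config):
    return generate_genome_annotation(small_config)


@pytest.fixture(scope="session")
def small_truth(small_config, small_genome):
    genome, features = small_genome
    return generate_true_methylome(genome, features, small_config)
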