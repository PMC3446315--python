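import numpy as np
import pandas as pd
import pytest

from medipkit import synthetic as syn


@pytest.fixture(scope="session")
def small_config():
    """A small but fully featured simulation: one 300-kb chromosome."""
    return syn.SimulationConfig(
        n_chroms=1,
        chrom_length=300_000,
        n_cgis_per_chrom=20,
        genes_per_chrom=12,
        library_size=100_000,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return syn.simulate_genome(small_config)


@pytest.fixture(scope="session")
def small_features(small_genome):
    return small_genome.annotate()


def three_gene_models():
    """Hand-built gene models on a 100-kb chromosome.

    gA: + strand [10000, 20000), TSS 10000, 3'UTR [19500, 20000)
    gB: - strand [40000, 50000), TSS 49999, 3'UTR [40000, 40500)
    gC: + strand [70000, 80000)
    """
    return pd.DataFrame(
        {
            "chrom": ["chr1"] * 3,
            "start": [10000, 40000, 70000],
            "end": [20000, 50000, 80000],
            "strand": ["+", "-", "+"],
            "gene_id": ["gA", "gB", "gC"],
            "utr3_len": [500, 500, 500],
        }
    )


@pytest.fixture
def gene_fixture():
    return three_gene_models()


def feature_table(n_feat=2000, classes=("CGI_INTRAGENIC", "CGI_PROMOTER", "LCP", "CDS")):
    """Synthetic annotated feature table with evenly tiled classes."""
    reps = int(np.ceil(n_feat / len(classes)))
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(n_feat) * 1000,
            "end": np.arange(n_feat) * 1000 + 500,
            "name": [f"F{i:05d}" for i in range(n_feat)],
            "feature_class": np.tile(classes, reps)[:n_feat],
        }
    )
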