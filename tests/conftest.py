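import numpy as np
import pandas as pd
import pytest

from neighborcorr.genome_pairs import GeneTable, neighbor_pairs
from neighborcorr.synthetic_data import (
    SimulationConfig,
    simulate_expression,
    simulate_genome,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_genes():
    """Six genes on two chromosomes with mixed strands (1-based coords)."""
    df = pd.DataFrame(
        {
            "gene_id": ["a1", "a2", "a3", "a4", "b1", "b2"],
            "chromosome": ["chr1"] * 4 + ["chr2"] * 2,
            "start": [1000, 5000, 9000, 20000, 2000, 8000],
            "end": [2000, 6500, 9500, 21000, 3000, 9000],
            "strand": ["+", "-", "+", "-", "+", "+"],
            "biotype": ["protein_coding"] * 6,
        }
    )
    df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"])
    return GeneTable(df)


@pytest.fixture(scope="session")
def small_cfg():
    """Small but realistic simulation: 2 chromosomes x 300 genes, 100 experiments."""
    return SimulationConfig(
        n_chromosomes=2,
        genes_per_chromosome=300,
        n_experiments=100,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_genome(small_cfg):
    return simulate_genome(small_cfg)


@pytest.fixture(scope="session")
def small_expression(small_cfg, small_genome):
    return simulate_expression(small_genome, small_cfg)


@pytest.fixture(scope="session")
def small_pairs(small_genome):
    return neighbor_pairs(small_genome, k=50)
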