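import numpy as np
import pandas as pd
import pytest

from methylome_kit import (SimulationConfig, assign_true_methylome,
                           build_context_index, simulate_counts,
                           simulate_genome)


def make_counts(rows):
    """Count table from (chrom, pos, strand, context, c, t) tuples."""
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context",
                       "c_count", "t_count"])


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=11, genome_length=120_000,
                            chromosome_count=2, gene_count=15, te_count=25)


@pytest.fixture(scope="session")
def dataset(small_config):
    """One simulated dataset shared across tests (read-only)."""
    genome, features = simulate_genome(small_config)
    truth = assign_true_methylome(genome, features, small_config)
    rep1, rep2 = simulate_counts(truth, small_config, n_replicates=2)
    return dict(config=small_config, genome=genome, features=features,
                truth=truth, rep1=rep1, rep2=rep2,
                index=truth[["chrom", "pos", "strand", "context"]])


@pytest.fixture(scope="session")
def flat_dataset():
    """High-coverage counts from a uniform 0.5 methylome, no conversion
    error — the no-signal baseline for profile flatness checks."""
    config = SimulationConfig(seed=23, genome_length=100_000,
                              chromosome_count=1, gene_count=12, te_count=10,
                              mean_coverage=50, conversion_failure=0.0)
    genome, features = simulate_genome(config)
    index = build_context_index(genome)
    truth = index.copy()
    truth["true_level"] = 0.5
    counts = simulate_counts(truth, config, n_replicates=1)[0]
    return dict(config=config, genome=genome, features=features,
                counts=counts, index=index)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
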