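"""Shared fixtures: simulated datasets are built once per session."""

import numpy as np
import pytest

from polykit.sim import SimConfig, simulate_genome, simulate_methylome, simulate_counts


@pytest.fixture(scope="session")
def default_sim():
    """Full default allopolyploid genome (7 groups x ABCD x 300 kb)."""
    return simulate_genome(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_kmer_matrix(default_sim):
    from polykit.phasing import count_kmers

    return count_kmers(default_sim.genome, k=15)


@pytest.fixture(scope="session")
def default_assignment(default_kmer_matrix):
    from polykit.phasing import select_differential_kmers, cluster_subgenomes

    diff = select_differential_kmers(default_kmer_matrix)
    return cluster_subgenomes(diff)


@pytest.fixture(scope="session")
def small_config():
    """Two homoeologous groups at 120 kb - fast but structurally complete."""
    return SimConfig(seed=7, n_groups=2, chrom_len=120_000, n_genes_per_chrom=10,
                     te_copies_per_chrom=3, monomer_copies=30)


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_genome(small_config)


@pytest.fixture(scope="session")
def meth_config():
    """Conditions for methylome recovery runs: planted gbM fraction 0.3,
    CG body level 0.6 vs background 0.10, depth 30."""
    return SimConfig(seed=2, n_groups=2, chrom_len=100_000, n_genes_per_chrom=25,
                     te_copies_per_chrom=3, monomer_copies=30, gbm_fraction=0.3,
                     read_depth=30.0)


@pytest.fixture(scope="session")
def meth_sim(meth_config):
    sim = simulate_genome(meth_config)
    cyt, gbm_truth = simulate_methylome(sim.genome, sim.genes, sim.tes, meth_config)
    return sim, cyt, gbm_truth
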