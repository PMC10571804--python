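import numpy as np
import pandas as pd
import pytest

from tadadiff.genes import build_gene_table
from tadadiff.occupancy import occupancy_tracks
from tadadiff.simulate import SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def tiny_config():
    """Small genome for fast end-to-end tests: 1 chromosome, 30 genes."""
    return SimConfig(genome_length=300_000, n_chromosomes=1, n_genes=30,
                     libsize=500_000, seed=11)


@pytest.fixture(scope="session")
def tiny_experiment(tiny_config):
    return simulate_experiment(tiny_config)


@pytest.fixture(scope="session")
def default_experiment():
    """One full-size experiment under the default study conditions."""
    return simulate_experiment(SimConfig(seed=11))


@pytest.fixture(scope="session")
def default_tracks(default_experiment):
    exp = default_experiment
    return occupancy_tracks(exp.counts, exp.samples)


@pytest.fixture(scope="session")
def default_gene_table(default_experiment, default_tracks):
    exp = default_experiment
    return build_gene_table(default_tracks, exp.genes, exp.fragments,
                            n_perm=1000, seed=11)


def manual_fragment_map(bounds, chrom="chr1"):
    """Fragment map from explicit cut boundaries, e.g. [0, 200, 500, 1000]."""
    starts, ends = bounds[:-1], bounds[1:]
    return pd.DataFrame(
        {
            "fragment_id": [f"frag_{i:07d}" for i in range(len(starts))],
            "chrom": chrom,
            "start": starts,
            "end": ends,
        }
    )


def manual_genes(spans, chrom="chr1", biotype="protein_coding"):
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(len(spans))],
            "chrom": chrom,
            "start": [s for s, _ in spans],
            "end": [e for _, e in spans],
            "strand": "+",
            "biotype": biotype,
        }
    )
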