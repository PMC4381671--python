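import numpy as np
import pandas as pd
import pytest

from ccgpipe.annotation import Exon, Gene, GeneAnnotation
from ccgpipe.counts import BED_COLUMNS, CountMatrix
from ccgpipe.synthetic_data import SimulationConfig, build_toy_annotation, build_truth

TIMES = np.arange(12) * 2.0


@pytest.fixture(scope="session")
def times():
    return TIMES.copy()


@pytest.fixture
def two_gene_annotation():
    """Two disjoint single-exon genes on one chromosome."""
    return GeneAnnotation(
        [
            Gene("gA", "chr1", "+", 1000, 3000),
            Gene("gB", "chr1", "-", 5000, 8000),
        ],
        chrom_sizes={"chr1": 20000},
    )


@pytest.fixture
def overlapping_annotation():
    """Two single-exon genes sharing a 500 bp overlap."""
    return GeneAnnotation(
        [
            Gene("gA", "chr1", "+", 1000, 3000),
            Gene("gB", "chr1", "-", 2500, 5000),
        ],
        chrom_sizes={"chr1": 20000},
    )


def make_reads(rows):
    """rows: (chrom, start, end, sample, strand)."""
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])
    df["score"] = 0
    return df[BED_COLUMNS]


@pytest.fixture
def small_config():
    return SimulationConfig(n_genes=30, n_overlap_pairs=2, frac_rhythmic=0.5, seed=7)


@pytest.fixture
def small_bundle(small_config):
    ann = build_toy_annotation(small_config)
    truth = build_truth(small_config, ann.gene_ids)
    return small_config, ann, truth


def nb_matrix(rng, mu, n_genes, nt=12, phi=0.05):
    """Seeded NB draws at constant mean, var = mu + phi mu^2."""
    var = mu + phi * mu * mu
    r = mu * mu / (var - mu)
    return rng.negative_binomial(r, r / (r + mu), size=(n_genes, nt))


def timecourse_matrix(X, assay="rna"):
    from ccgpipe.counts import time_label

    labels = [time_label(h) for h in TIMES[: X.shape[1]]]
    return CountMatrix(
        pd.DataFrame(X, index=[f"g{i:04d}" for i in range(X.shape[0])], columns=labels),
        assay=assay,
    )
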