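"""Shared fixtures: a tiny deterministic genome/gene set and a small
synthetic-epigenome configuration used by the module tests."""

from __future__ import annotations

import numpy as np
import pytest

from epidyn.intervals import GeneModel, GenomeIndex, GenomicInterval
from epidyn.simulate import SimulationConfig


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_genome():
    return GenomeIndex({"chr1": 100_000, "chr2": 60_000})


def make_gene(gene_id, chrom, start, end, strand, exon_bounds, thick=None):
    exons = tuple(GenomicInterval(chrom, a, b, strand) for a, b in exon_bounds)
    return GeneModel(
        gene_id=gene_id,
        interval=GenomicInterval(chrom, start, end, strand),
        exons=exons,
        thick_start=thick[0] if thick else None,
        thick_end=thick[1] if thick else None,
    )


@pytest.fixture(scope="session")
def two_gene_fixture():
    """Two genes on chr1: geneA (3 exons, UTRs) nested inside the long
    intron of geneB, so every geneA feature competes with 'intron' in the
    precedence order."""
    gene_a = make_gene(
        "geneA", "chr1", 20_000, 26_000, "+",
        [(20_000, 21_000), (22_000, 23_000), (24_000, 26_000)],
        thick=(20_500, 24_800),
    )
    gene_b = make_gene(
        "geneB", "chr1", 2_000, 40_000, "+",
        [(2_000, 2_600), (39_000, 40_000)],
        thick=(2_300, 39_500),
    )
    return [gene_b, gene_a]


@pytest.fixture(scope="session")
def small_sim_config():
    """Desk-top-scale simulation: two 300 kb chromosomes, 60 genes."""
    return SimulationConfig(
        seed=7,
        n_chroms=2,
        chrom_size=300_000,
        n_genes=60,
        n_stable_lmr=8,
        n_new_lmr=5,
        n_specific_lmr=3,
        n_constitutive_lmr=3,
        n_new_enhancer=2,
        n_stable_enhancer=2,
        n_demeth_gene=3,
        n_hypermeth_gene=3,
        n_t1_peak=3,
        n_common_peak=4,
        n_t2_peak=3,
        enhancer_length=4000,
        big_gap_length=7000,
        depth=200_000,
    )
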