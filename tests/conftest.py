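import numpy as np
import pytest

from devtx import counting, simulate
from devtx.annotation import GeneModel, GenomeAnnotation
from devtx.intervals import GenomicInterval


@pytest.fixture(scope="session")
def toy_annotation() -> GenomeAnnotation:
    """Two genes on a 10 kb chromosome with known exon/intron geometry.

    geneX: exons [1000,1400) and [1900,2300), intron [1400,1900)
    geneY: single exon [3000,3500)
    """
    genes = {
        "geneX": GeneModel(
            "geneX",
            "chr1",
            "+",
            [
                GenomicInterval("chr1", 1000, 1400, "+"),
                GenomicInterval("chr1", 1900, 2300, "+"),
            ],
        ),
        "geneY": GeneModel("geneY", "chr1", "-", [GenomicInterval("chr1", 3000, 3500, "-")]),
    }
    return GenomeAnnotation(genes=genes, chromosome_lengths={"chr1": 10_000})


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete simulated data set shared across tests."""
    cfg = simulate.SimulationConfig.small()
    annotation = simulate.simulate_annotation(cfg, seed=11)
    truth = simulate.simulate_expression(cfg, seed=12, annotation=annotation)
    alignments = simulate.simulate_alignments(truth, annotation, cfg, seed=13)
    return cfg, annotation, truth, alignments


@pytest.fixture(scope="session")
def small_counts(small_sim):
    cfg, annotation, truth, alignments = small_sim
    index = counting.GenomeIndex(annotation)
    tables = [
        counting.assign_reads(df, annotation, stage=stage, index=index)
        for stage, df in alignments.items()
    ]
    return annotation, tables


@pytest.fixture(scope="session")
def small_expression(small_counts):
    annotation, tables = small_counts
    return annotation, tables, counting.build_expression_matrix(tables, annotation)
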