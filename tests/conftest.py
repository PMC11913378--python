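import numpy as np
import pytest

from tadboundary.core import GeneModel, GenomicInterval


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_gene(gene_id, chrom, strand, exon_bounds):
    """Gene from a list of (start, end) exon pairs (genomic order)."""
    exons = tuple(GenomicInterval(chrom, s, e, strand) for s, e in exon_bounds)
    return GeneModel(gene_id, chrom, strand, exon_bounds[0][0],
                     exon_bounds[-1][1], exons=exons)


@pytest.fixture
def seven_exon_gene():
    """Plus-strand gene with 7 exons of 100 bp separated by 2.9 kb
    introns, spanning chr1:10000-28100 (introns clear the ±1 kb promoter
    window)."""
    bounds = [(10000 + i * 3000, 10000 + i * 3000 + 100) for i in range(7)]
    return make_gene("g7", "chr1", "+", bounds)


@pytest.fixture
def minus_gene():
    """Minus-strand gene chr1:50000-56000 with 3 exons."""
    return make_gene("gm", "chr1", "-",
                     [(50000, 51000), (52000, 53000), (55000, 56000)])
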