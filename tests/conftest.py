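import numpy as np
import pytest

from enhload.core import ChromSizes, GeneRecord, GenomicInterval


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def three_gene_setup():
    """The hand-worked regulatory-domain example: three genes on a 1 Mb chrom."""
    sizes = ChromSizes({"chr1": 1_000_000})
    genes = [
        GeneRecord("g1", "chr1", "+", 100_000),
        GeneRecord("g2", "chr1", "+", 300_000),
        GeneRecord("g3", "chr1", "-", 310_000),
    ]
    return sizes, genes


def random_peaks(rng, n, chroms=("chr1", "chr2"), max_pos=1_000_000, with_stats=False):
    peaks = []
    for _ in range(n):
        chrom = str(rng.choice(chroms))
        start = int(rng.integers(0, max_pos - 1))
        end = start + int(rng.integers(1, 5_000))
        fc = float(rng.uniform(0, 10)) if with_stats else None
        q = float(rng.uniform(0, 10)) if with_stats else None
        peaks.append(GenomicInterval(chrom, start, end, fold_change=fc, neg_log10_q=q))
    return peaks
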