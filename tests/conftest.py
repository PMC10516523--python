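import numpy as np
import pytest

from kaskit.intervals import ChromSizes, GeneModel, GenomicInterval


@pytest.fixture
def sizes():
    return ChromSizes({"chr1": 100_000, "chr2": 50_000})


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_intervals(rng, n, chrom="chr1", max_pos=10_000, max_width=500,
                     stranded=False):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, max_pos - 1))
        width = int(rng.integers(1, max_width + 1))
        end = min(start + width, max_pos)
        strand = rng.choice(["+", "-"]) if stranded else "."
        out.append(GenomicInterval(chrom, start, end, strand=str(strand)))
    return out


def base_set(intervals, chrom="chr1"):
    """Per-base membership oracle."""
    out = set()
    for iv in intervals:
        if iv.chrom == chrom:
            out.update(range(iv.start, iv.end))
    return out


@pytest.fixture
def simple_genes():
    return [
        GeneModel(GenomicInterval("chr1", 10_000, 20_000, strand="+"), "gplus"),
        GeneModel(GenomicInterval("chr1", 40_000, 50_000, strand="-"), "gminus"),
    ]
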