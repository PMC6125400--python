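import random

import pytest

from markconcord.io_formats import GeneModel, Peak


@pytest.fixture
def rnd():
    """Seeded stdlib RNG for test-local randomness."""
    return random.Random(20240917)


@pytest.fixture
def small_genes():
    """A handful of genes on two chromosomes, both strands."""
    return [
        GeneModel("GA", "chr1", 10_000, 18_000, "+"),
        GeneModel("GB", "chr1", 40_000, 52_000, "-"),
        GeneModel("GC", "chr1", 80_000, 85_000, "+"),
        GeneModel("GD", "chr2", 5_000, 9_000, "-"),
    ]


def random_peaks(rnd, n, chroms=("chr1",), span=5000, max_width=300, replicate_id="", condition=""):
    """n random peaks in a small coordinate space (shared by oracle tests)."""
    peaks = []
    for _ in range(n):
        chrom = rnd.choice(chroms)
        start = rnd.randrange(0, span - 1)
        width = rnd.randrange(1, max_width)
        peaks.append(Peak(chrom, start, min(start + width, span), "",
                          None, replicate_id, condition))
    return peaks
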