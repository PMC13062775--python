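import numpy as np
import pytest

from pg4scape.io_formats import BinGrid, GenomeIndex, GenomicInterval


@pytest.fixture
def toy_genome() -> GenomeIndex:
    return GenomeIndex([("chr1", 500_000), ("chr2", 230_000)])


@pytest.fixture
def toy_grid(toy_genome) -> BinGrid:
    # chr1: 10 full 50 kb bins; chr2: 4 full + one 30 kb terminal bin
    return BinGrid(toy_genome, 50_000)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_intervals(rng, chrom, chrom_len, n, max_len=400, stranded=False):
    """n random (possibly overlapping) intervals on one chromosome."""
    starts = rng.integers(0, chrom_len - max_len, size=n)
    lengths = rng.integers(1, max_len, size=n)
    strands = rng.choice(["+", "-"], size=n) if stranded else ["."] * n
    return [
        GenomicInterval(chrom, int(s), int(s + l), str(st))
        for s, l, st in zip(starts, lengths, strands)
    ]
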