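import numpy as np
import pandas as pd
import pytest

from regenrich.intervals import Genome, GenomicInterval, PeakSet


@pytest.fixture
def small_genome() -> Genome:
    return Genome.from_sizes([("1", 10_000), ("2", 10_000), ("3", 10_000)])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_peakset(rng, genome, n=200, max_len=500, shape="broad") -> PeakSet:
    ivs = []
    names = genome.names
    sizes = genome.sizes
    for _ in range(n):
        chrom = names[int(rng.integers(len(names)))]
        start = int(rng.integers(0, sizes[chrom] - max_len))
        length = int(rng.integers(1, max_len))
        ivs.append(GenomicInterval(chrom, start, start + length))
    return PeakSet(ivs, shape_class=shape)


def bitmap_coverage(peaks: PeakSet, genome: Genome) -> int:
    """Per-base boolean-array oracle for covered bp."""
    total = 0
    for chrom, length in genome.chromosomes:
        mask = np.zeros(length, dtype=bool)
        for iv in peaks:
            if iv.chrom == chrom:
                mask[iv.start:iv.end] = True
        total += int(mask.sum())
    return total


def bitmap_consensus(peaksets, genome: Genome, min_support: int):
    """Per-base vote-count oracle: list of (chrom, start, end, max_support)."""
    out = []
    for chrom, length in genome.chromosomes:
        votes = np.zeros(length, dtype=np.int64)
        for ps in peaksets:
            mask = np.zeros(length, dtype=bool)
            for iv in ps:
                if iv.chrom == chrom:
                    mask[iv.start:iv.end] = True
            votes += mask
        above = votes >= min_support
        i = 0
        while i < length:
            if above[i]:
                j = i
                while j + 1 < length and above[j + 1]:
                    j += 1
                out.append((chrom, i, j + 1, int(votes[i:j + 1].max())))
                i = j + 1
            else:
                i += 1
    return out
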