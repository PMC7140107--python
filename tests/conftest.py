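import numpy as np
import pytest

from hypoblocks.genome_intervals import GenomeModel, Interval, IntervalSet


@pytest.fixture
def small_genome() -> GenomeModel:
    return GenomeModel((("chr1", 1000), ("chr2", 500)))


@pytest.fixture
def mb_genome() -> GenomeModel:
    return GenomeModel((("chr1", 600_000), ("chr2", 400_000)))


def random_interval_set(
    genome: GenomeModel, n: int, rng: np.random.Generator, max_len: int = 100
) -> IntervalSet:
    ivs = []
    for _ in range(n):
        chrom, length = genome.chromosomes[int(rng.integers(len(genome.chromosomes)))]
        span = int(rng.integers(1, max_len + 1))
        start = int(rng.integers(0, length - span + 1))
        ivs.append(Interval(chrom, start, start + span))
    return IntervalSet(ivs, "random")


def per_base_mask(intervals: IntervalSet, genome: GenomeModel) -> dict[str, np.ndarray]:
    """Brute-force per-base boolean coverage; the oracle for all interval algebra."""
    masks = {c: np.zeros(length, dtype=bool) for c, length in genome.chromosomes}
    for iv in intervals:
        masks[iv.chrom][iv.start : iv.end] = True
    return masks
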