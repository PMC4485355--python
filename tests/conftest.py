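import numpy as np
import pytest

from cyclepeaks.intervals import GenomeTable, GenomicInterval, PeakSet


@pytest.fixture
def genome():
    return GenomeTable({"chr2L": 1_000_000, "chr2R": 800_000, "chrX": 600_000})


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_peaks(genome, spec):
    """spec: list of (chrom, start, end[, name[, summit]])."""
    ivs = []
    for i, s in enumerate(spec):
        chrom, start, end = s[:3]
        name = s[3] if len(s) > 3 else f"p{i}"
        summit = s[4] if len(s) > 4 else None
        ivs.append(GenomicInterval(chrom, start, end, name, summit=summit))
    return PeakSet(ivs, genome)


@pytest.fixture
def peaks_factory(genome):
    def factory(spec):
        return make_peaks(genome, spec)

    return factory
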