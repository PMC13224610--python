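import numpy as np
import pytest

from g4shift.intervals import GenomeDef, GenomicInterval, IntervalSet
from g4shift.simulate import SynthGenomeSpec, make_genome


@pytest.fixture(scope="session")
def small_genome():
    """100 kb single-chromosome genome with 50 planted motifs."""
    spec = SynthGenomeSpec(chrom_lengths=(100_000,), n_motifs=50, min_spacing=50, seed=11)
    seqs, genome, truth = make_genome(spec)
    return seqs, genome, truth


@pytest.fixture(scope="session")
def desk_genome():
    """Desk-scale study genome: 1 Mb, motif footprint ~1% (476 x 21 bp)."""
    spec = SynthGenomeSpec(chrom_lengths=(1_000_000,), n_motifs=476, min_spacing=50, seed=7)
    seqs, genome, truth = make_genome(spec)
    return seqs, genome, truth


@pytest.fixture
def toy_genome():
    return GenomeDef.from_pairs([("chr1", 1000), ("chr2", 500)])


def iv(chrom, start, end, **kw):
    return GenomicInterval(chrom, start, end, **kw)


def iset(genome, *triples, role="events"):
    return IntervalSet((GenomicInterval(*t) for t in triples), genome, role)


@pytest.fixture
def make_set(toy_genome):
    def _make(*triples, role="events"):
        return iset(toy_genome, *triples, role=role)

    return _make
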