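import numpy as np
import pytest

from neoexon.core import GeneAnnotation, GenomeSequence, Interval, Transcript
from neoexon.simulate import default_config, simulate_all


@pytest.fixture(scope="session")
def sim():
    """One shared synthetic dataset (seed 1) for the heavier tests."""
    return simulate_all(default_config(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_genome():
    return GenomeSequence("chr1", "ACGTACGTACGTACGTACGT")


def make_transcript(tid, gene, exons, strand="+", seq="chr1", cds=None):
    return Transcript(
        tid,
        gene,
        [Interval(seq, s, e, strand) for s, e in exons],
        cds=[Interval(seq, s, e, strand) for s, e in cds] if cds else None,
    )


@pytest.fixture
def two_isoform_gene():
    """Cassette-exon gene: isoform 2 skips the middle exon."""
    ann = GeneAnnotation()
    ann.add_transcript(make_transcript("t1", "g1", [(0, 100), (200, 260), (400, 500)]))
    ann.add_transcript(make_transcript("t2", "g1", [(0, 100), (400, 500)]))
    return ann.genes["g1"]
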