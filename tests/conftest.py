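import numpy as np
import pytest

from a3sig import (
    MutationRecord,
    OrientedContext,
    ReferenceSequence,
    make_genome,
)


@pytest.fixture(scope="session")
def genome_200kb() -> ReferenceSequence:
    return make_genome(200_000, 0.4, seed=11)


@pytest.fixture(scope="session")
def genome_2mb() -> ReferenceSequence:
    return make_genome(2_000_000, 0.4, seed=12)


def make_context(
    kmer: str,
    alt_oriented: str,
    sample_id: str = "s1",
    chrom: str = "chr1",
    pos: int = 100,
    strand: str = "+",
    condition: str = "",
    flagged: bool = False,
) -> OrientedContext:
    """Hand-built oriented context for unit tests (fields self-consistent)."""
    flank = len(kmer) // 2
    center = kmer[flank]
    if strand == "+":
        ref, alt = center, alt_oriented
    else:
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        ref, alt = comp[center], comp[alt_oriented]
    mut = MutationRecord(sample_id, condition, chrom, pos, ref, alt)
    return OrientedContext(mut, kmer, strand, alt_oriented, flagged)


@pytest.fixture
def ctx_factory():
    return make_context
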