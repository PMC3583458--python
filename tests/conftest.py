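from __future__ import annotations

import pytest

from homeocat.formats_io import AlignedRead, GenomicPosition
from homeocat.snp_index import SnpIndex, SnpRecord


def make_read(
    chrom="chr1",
    pos=0,
    seq="ACGT",
    cigar=None,
    quals=None,
    name="r1",
    flag=0,
):
    if cigar is None:
        cigar = (("M", len(seq)),)
    if quals is None:
        quals = tuple([35] * len(seq))
    return AlignedRead(
        name=name,
        position=GenomicPosition(chrom, pos),
        cigar=tuple(cigar),
        seq=seq,
        quals=tuple(quals),
        flag=flag,
    )


def make_index(records, reference_name="test"):
    """records: iterable of (chrom, pos, ref, alleles_A, alleles_D)."""
    index = SnpIndex(reference_name)
    for chrom, pos, ref, a, d in records:
        index.add(SnpRecord.make(chrom, pos, ref, a.split(","), d.split(",")))
    return index


@pytest.fixture
def toy_index():
    return make_index(
        [
            ("chr1", 10, "A", "G", "A"),
            ("chr1", 20, "C", "C", "T"),
            ("chr1", 30, "G", "G", "T"),
        ]
    )
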