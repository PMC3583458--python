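"""Readers, writers, and coordinate plumbing for external formats.

All internal coordinates are 0-based, half-open.  Serialized text formats
(pileup, SNP index, methylation report) use 1-based positions to match the
samtools/VCF convention; conversion happens here and nowhere else.
"""

from __future__ import annotations

import io
from collections.abc import Iterable, Iterator
from dataclasses import dataclass, field

__all__ = [
    "GenomicPosition",
    "PileupColumn",
    "AlignedRead",
    "FormatError",
    "read_fasta",
    "parse_mpileup_line",
    "read_mpileup",
    "read_to_reference_pairs",
    "aligned_read_from_pysam",
]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True, order=True)
class GenomicPosition:
    """A 0-based reference coordinate."""

    chrom: str
    pos: int

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos} on {self.chrom}")


@dataclass
class PileupColumn:
    """One resolved column of a samtools-style text pileup.

    ``base_counts`` holds A/C/G/T counts only; deletion placeholders,
    reference skips, and N bases are excluded, so the counts may sum to
    less than ``depth``.
    """

    position: GenomicPosition
    ref_base: str
    depth: int
    base_counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.base_counts.values())


# SAM flag bits we care about
_FLAG_PAIRED = 0x1
_FLAG_UNMAPPED = 0x4
_FLAG_REVERSE = 0x10
_FLAG_READ1 = 0x40
_FLAG_READ2 = 0x80
_FLAG_SECONDARY = 0x100
_FLAG_SUPPLEMENTARY = 0x800


@dataclass
class AlignedRead:
    """A mapped (or unmapped) read with SAM-style fields.

    ``cigar`` is a sequence of ``(op, length)`` pairs using the SAM
    single-character operation alphabet (M I D N S H P = X).
    """

    name: str
    position: GenomicPosition | None
    cigar: tuple[tuple[str, int], ...]
    seq: str
    quals: tuple[int, ...]
    flag: int = 0

    @property
    def is_mapped(self) -> bool:
        return self.position is not None and not (self.flag & _FLAG_UNMAPPED)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & _FLAG_REVERSE)

    @property
    def is_paired(self) -> bool:
        return bool(self.flag & _FLAG_PAIRED)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flag & _FLAG_SECONDARY)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flag & _FLAG_SUPPLEMENTARY)

    def __post_init__(self) -> None:
        if self.is_mapped:
            consumed = sum(n for op, n in self.cigar if op in "MIS=X")
            if consumed != len(self.seq):
                raise ValueError(
                    f"read {self.name}: CIGAR consumes {consumed} bases "
                    f"but sequence has {len(self.seq)}"
                )


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into ``{name: sequence}``.

    Names are the first whitespace-delimited token of each header.
    Sequences are uppercased.  Duplicate names, headerless sequence, and
    empty records raise :class:`FormatError` naming the offending line.
    """
    seqs: dict[str, str] = {}
    name: str | None = None
    chunks: list[str] = []
    header_line = 0

    def _flush() -> None:
        if name is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"line {header_line}: record '{name}' has no sequence")
        seqs[name] = seq.upper()

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                _flush()
                token = line[1:].split()
                if not token:
                    raise FormatError(f"line {lineno}: empty FASTA header")
                if token[0] in seqs:
                    raise FormatError(f"line {lineno}: duplicate record name '{token[0]}'")
                name = token[0]
                chunks = []
                header_line = lineno
            else:
                if name is None:
                    raise FormatError(f"line {lineno}: sequence before any header")
                chunks.append(line.strip())
    _flush()
    return seqs


def parse_mpileup_line(line: str) -> PileupColumn:
    """Parse one line of the 6-column samtools mpileup text dialect.

    '.'/',' resolve to the reference base; upper/lowercase mismatch
    characters count toward their base; '^'+mapq prefixes, '$' suffixes,
    and '+n'/'-n' indel substrings are consumed without counting; '*',
    '>', '<', and N are consumed as columns but excluded from
    base_counts.  Lines with extra columns (e.g. the mapping-quality
    dialect) are rejected.
    """
    fields = line.rstrip("\n").split("\t")
    if len(fields) != 6:
        raise FormatError(
            f"expected 6 tab-separated pileup columns, got {len(fields)} "
            "(mapping-quality pileup dialects are not accepted)"
        )
    chrom, pos_s, ref, depth_s, bases, _quals = fields
    try:
        pos1 = int(pos_s)
        depth = int(depth_s)
    except ValueError as exc:
        raise FormatError(f"non-integer position/depth in pileup line: {line!r}") from exc
    if pos1 < 1:
        raise FormatError(f"pileup position must be 1-based positive, got {pos1}")
    ref = ref.upper()

    counts: dict[str, int] = {}
    consumed = 0
    i = 0
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            i += 2  # caret + mapping quality char
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise FormatError(f"malformed indel in pileup bases: {bases!r}")
            ilen = int(bases[i + 1 : j])
            i = j + ilen
            continue
        consumed += 1
        if c in ".,":
            if ref not in "ACGT":
                pass  # reference N: observation uncountable
            else:
                counts[ref] = counts.get(ref, 0) + 1
        else:
            cu = c.upper()
            if cu in "ACGT":
                counts[cu] = counts.get(cu, 0) + 1
            elif cu == "N" or c in "*><":
                pass
            else:
                raise FormatError(f"unrecognized pileup base symbol {c!r} in {bases!r}")
        i += 1

    if consumed != depth:
        raise FormatError(
            f"pileup depth {depth} does not match {consumed} resolved base symbols"
        )
    return PileupColumn(
        position=GenomicPosition(chrom, pos1 - 1),
        ref_base=ref,
        depth=depth,
        base_counts=counts,
    )


def read_mpileup(source) -> Iterator[PileupColumn]:
    """Yield :class:`PileupColumn` from a path or an open text handle."""
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        fh: Iterable[str] = open(source)
        close = True
    else:
        fh = source
        close = False
    try:
        for line in fh:
            if line.strip():
                yield parse_mpileup_line(line)
    finally:
        if close and isinstance(fh, io.IOBase):
            fh.close()


def read_to_reference_pairs(read: AlignedRead) -> list[tuple[int, int]]:
    """Map read offsets to reference positions along the alignment.

    Returns one ``(read_offset, reference_pos)`` pair per M/=/X column.
    Insertions, deletions, reference skips, and clips contribute no
    pairs.  Unmapped reads return an empty list.
    """
    if not read.is_mapped:
        return []
    pairs: list[tuple[int, int]] = []
    roff = 0
    rpos = read.position.pos
    for op, length in read.cigar:
        if op in "M=X":
            for k in range(length):
                pairs.append((roff + k, rpos + k))
            roff += length
            rpos += length
        elif op in "IS":
            roff += length
        elif op in "DN":
            rpos += length
        elif op in "HP":
            pass
        else:
            raise ValueError(f"unknown CIGAR operation {op!r}")
    return pairs


def aligned_read_from_pysam(aln, chrom: str | None = None) -> AlignedRead:
    """Convert a :class:`pysam.AlignedSegment` to :class:`AlignedRead`."""
    if aln.is_unmapped:
        position = None
        cigar: tuple[tuple[str, int], ...] = ()
    else:
        position = GenomicPosition(chrom or aln.reference_name, aln.reference_start)
        cigar = tuple((op, length) for op, length in _cigar_from_pysam(aln))
    quals = tuple(aln.query_qualities) if aln.query_qualities is not None else ()
    return AlignedRead(
        name=aln.query_name,
        position=position,
        cigar=cigar,
        seq=(aln.query_sequence or "").upper(),
        quals=quals,
        flag=aln.flag,
    )


_PYSAM_OPS = "MIDNSHP=X"


def _cigar_from_pysam(aln):
    for code, length in aln.cigartuples or ():
        yield _PYSAM_OPS[code], length
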