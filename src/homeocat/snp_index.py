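"""Build, classify, summarize, serialize, and merge the homoeo-SNP index.

The index records fixed single-nucleotide differences between the two
subgenomes (labelled A and D by default) called from two per-genome
pileups against a common reference.
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_left, bisect_right
from collections.abc import Iterable, Iterator
from dataclasses import dataclass, field
from enum import Enum

from .formats_io import FormatError, GenomicPosition, PileupColumn

__all__ = [
    "GENOME_A",
    "GENOME_D",
    "SnpType",
    "SnpRecord",
    "SnpIndex",
    "SiteVerdict",
    "SiteCall",
    "IndexParams",
    "classify_snp",
    "call_site",
    "build_index",
    "merge_indexes",
    "index_summary",
    "summarize_pair_counts",
    "IndexSummary",
    "write_index",
    "read_index",
    "export_gsnap",
    "write_vcf",
]

log = logging.getLogger(__name__)

GENOME_A = "A"
GENOME_D = "D"

_TRANSITION_PAIRS = (frozenset("AG"), frozenset("CT"))


class SnpType(str, Enum):
    transition = "transition"
    transversion = "transversion"
    multi_allele = "multi_allele"


class SiteVerdict(str, Enum):
    homoeo_snp = "homoeo_snp"
    allele_snp_A = "allele_snp_A"
    allele_snp_D = "allele_snp_D"
    no_call = "no_call"


def classify_snp(alleles_A: frozenset | set, alleles_D: frozenset | set) -> SnpType:
    """Classify a disjoint pair of per-genome allele sets.

    multi_allele if either set has more than one base; otherwise
    transition for A<->G and C<->T pairs, transversion for the rest.
    """
    a, d = frozenset(alleles_A), frozenset(alleles_D)
    if not a or not d:
        raise ValueError("allele sets must be non-empty")
    if a & d:
        raise ValueError(f"allele sets overlap: {sorted(a)} vs {sorted(d)}")
    if len(a) > 1 or len(d) > 1:
        return SnpType.multi_allele
    if a | d in _TRANSITION_PAIRS:
        return SnpType.transition
    return SnpType.transversion


@dataclass(frozen=True)
class SnpRecord:
    """One indexed homoeo-SNP site."""

    position: GenomicPosition
    ref_base: str
    alleles_A: frozenset
    alleles_D: frozenset
    snp_type: SnpType
    origin: str = "diploid_pileup"

    def __post_init__(self) -> None:
        if self.alleles_A & self.alleles_D:
            raise ValueError(
                f"{self.position.chrom}:{self.position.pos}: "
                "per-genome allele sets must be disjoint"
            )
        expected = classify_snp(self.alleles_A, self.alleles_D)
        if expected is not self.snp_type:
            raise ValueError(
                f"{self.position.chrom}:{self.position.pos}: snp_type "
                f"{self.snp_type.value} inconsistent with alleles (expected {expected.value})"
            )

    @classmethod
    def make(
        cls,
        chrom: str,
        pos: int,
        ref_base: str,
        alleles_A: Iterable[str],
        alleles_D: Iterable[str],
        origin: str = "diploid_pileup",
    ) -> "SnpRecord":
        a, d = frozenset(alleles_A), frozenset(alleles_D)
        return cls(
            position=GenomicPosition(chrom, pos),
            ref_base=ref_base.upper(),
            alleles_A=a,
            alleles_D=d,
            snp_type=classify_snp(a, d),
            origin=origin,
        )


class SnpIndex:
    """Coordinate-keyed collection of :class:`SnpRecord`.

    Supports O(1) point lookup and O(log n) interval queries per
    chromosome.  At most one record per reference position.
    """

    def __init__(self, reference_name: str = "", metadata: dict | None = None):
        self.reference_name = reference_name
        self.metadata: dict = dict(metadata or {})
        self._by_chrom: dict[str, dict[int, SnpRecord]] = {}
        self._sorted_cache: dict[str, list[int]] = {}

    def __len__(self) -> int:
        return sum(len(d) for d in self._by_chrom.values())

    def __contains__(self, key) -> bool:
        chrom, pos = key
        return pos in self._by_chrom.get(chrom, ())

    def get(self, chrom: str, pos: int) -> SnpRecord | None:
        return self._by_chrom.get(chrom, {}).get(pos)

    def add(self, record: SnpRecord) -> None:
        chrom = record.position.chrom
        bucket = self._by_chrom.setdefault(chrom, {})
        if record.position.pos in bucket:
            raise ValueError(
                f"duplicate index record at {chrom}:{record.position.pos}"
            )
        bucket[record.position.pos] = record
        self._sorted_cache.pop(chrom, None)

    def chromosomes(self) -> list[str]:
        return sorted(self._by_chrom)

    def _sorted_positions(self, chrom: str) -> list[int]:
        cached = self._sorted_cache.get(chrom)
        if cached is None:
            cached = sorted(self._by_chrom.get(chrom, ()))
            self._sorted_cache[chrom] = cached
        return cached

    def positions_in(self, chrom: str, start: int, end: int) -> list[int]:
        """Sorted record positions in the half-open interval [start, end)."""
        positions = self._sorted_positions(chrom)
        lo = bisect_left(positions, start)
        hi = bisect_right(positions, end - 1)
        return positions[lo:hi]

    def records(self) -> Iterator[SnpRecord]:
        """All records, sorted by chromosome then position."""
        for chrom in self.chromosomes():
            bucket = self._by_chrom[chrom]
            for pos in self._sorted_positions(chrom):
                yield bucket[pos]

    def copy(self) -> "SnpIndex":
        out = SnpIndex(self.reference_name, self.metadata)
        for rec in self.records():
            out.add(rec)
        return out


@dataclass(frozen=True)
class IndexParams:
    min_coverage: int = 4
    maf_threshold: float = 0.40
    fixation_threshold: float = 0.90

    def __post_init__(self) -> None:
        if not (0 < self.maf_threshold < 0.5 <= self.fixation_threshold <= 1):
            raise ValueError(
                "require 0 < maf_threshold < 0.5 <= fixation_threshold <= 1"
            )


@dataclass
class SiteCall:
    """Outcome of calling one position from the two per-genome pileups.

    ``allele_snps`` is the side channel of within-genome segregating
    bases detected at this position, as ``(genome_label, base)`` pairs
    (filled both when the verdict is an allele-SNP and when a shared
    qualifying base was reduced away from a homoeo-SNP record).
    """

    verdict: SiteVerdict
    record: SnpRecord | None = None
    allele_snps: tuple[tuple[str, str], ...] = ()


def _qualifying_alleles(col: PileupColumn, params: IndexParams) -> set[str]:
    total = col.total
    if total == 0:
        return set()
    freqs = {b: c / total for b, c in col.base_counts.items() if b in "ACGT"}
    major = max(freqs, key=freqs.get)
    if freqs[major] >= params.fixation_threshold:
        return {major}
    return {b for b, f in freqs.items() if f >= params.maf_threshold}


def call_site(
    col_A: PileupColumn,
    col_D: PileupColumn,
    params: IndexParams | None = None,
) -> SiteCall:
    """Call one reference position from aligned per-genome pileup columns.

    A genome's qualifying allele set is every base at frequency >=
    maf_threshold, collapsed to the major allele when it reaches
    fixation_threshold.  Bases qualifying in both genomes cannot
    discriminate, so each shared base is removed from whichever set has
    another allele left (recorded in the allele-SNP side channel); if the
    reduced sets are non-empty and disjoint the site is a homoeo-SNP.
    """
    params = params or IndexParams()
    if col_A.position != col_D.position:
        raise ValueError(
            f"pileup columns disagree on position: {col_A.position} vs {col_D.position}"
        )
    if col_A.total < params.min_coverage or col_D.total < params.min_coverage:
        return SiteCall(SiteVerdict.no_call)

    q_A = _qualifying_alleles(col_A, params)
    q_D = _qualifying_alleles(col_D, params)
    if not q_A or not q_D:
        return SiteCall(SiteVerdict.no_call)

    side: list[tuple[str, str]] = []
    red_A, red_D = set(q_A), set(q_D)
    for base in sorted(q_A & q_D):
        removed = False
        if len(red_A) > 1:
            red_A.discard(base)
            side.append((GENOME_A, base))
            removed = True
        if len(red_D) > 1:
            red_D.discard(base)
            side.append((GENOME_D, base))
            removed = True
        if not removed:
            # sole qualifying allele in both genomes: nothing to index
            pass

    if red_A and red_D and not (red_A & red_D):
        record = SnpRecord.make(
            col_A.position.chrom,
            col_A.position.pos,
            col_A.ref_base,
            red_A,
            red_D,
        )
        return SiteCall(SiteVerdict.homoeo_snp, record, tuple(side))

    # not indexable; report within-genome segregation if present
    if len(q_A) > 1:
        return SiteCall(
            SiteVerdict.allele_snp_A,
            allele_snps=tuple((GENOME_A, b) for b in sorted(q_A)),
        )
    if len(q_D) > 1:
        return SiteCall(
            SiteVerdict.allele_snp_D,
            allele_snps=tuple((GENOME_D, b) for b in sorted(q_D)),
        )
    return SiteCall(SiteVerdict.no_call)


@dataclass(frozen=True)
class AlleleSnpEntry:
    position: GenomicPosition
    genome: str
    base: str


def build_index(
    pileup_A: Iterable[PileupColumn],
    pileup_D: Iterable[PileupColumn],
    params: IndexParams | None = None,
    reference_name: str = "",
) -> tuple[SnpIndex, list[AlleleSnpEntry]]:
    """Coordinated merge-walk over two sorted pileup streams.

    Streams must be sorted by (chromosome, position) with chromosomes in
    lexicographic order.  Positions present in only one stream are
    no_call.  Returns the homoeo-SNP index and the allele-SNP side table.
    """
    params = params or IndexParams()
    index = SnpIndex(
        reference_name,
        metadata={
            "min_coverage": params.min_coverage,
            "maf_threshold": params.maf_threshold,
            "fixation_threshold": params.fixation_threshold,
        },
    )
    side_table: list[AlleleSnpEntry] = []

    def _checked(stream, label):
        last = None
        for col in stream:
            key = (col.position.chrom, col.position.pos)
            if last is not None and key <= last:
                raise FormatError(
                    f"pileup {label} not sorted: {key[0]}:{key[1] + 1} "
                    f"follows {last[0]}:{last[1] + 1}"
                )
            last = key
            yield key, col

    it_A = _checked(pileup_A, GENOME_A)
    it_D = _checked(pileup_D, GENOME_D)
    a = next(it_A, None)
    d = next(it_D, None)
    while a is not None and d is not None:
        if a[0] < d[0]:
            a = next(it_A, None)
        elif d[0] < a[0]:
            d = next(it_D, None)
        else:
            call = call_site(a[1], d[1], params)
            if call.verdict is SiteVerdict.homoeo_snp:
                index.add(call.record)
            for genome, base in call.allele_snps:
                side_table.append(AlleleSnpEntry(a[1].position, genome, base))
            a = next(it_A, None)
            d = next(it_D, None)
    # drain both streams so sort violations past the shorter one still raise
    for _ in it_A:
        pass
    for _ in it_D:
        pass
    return index, side_table


def merge_indexes(base: SnpIndex, additions: SnpIndex) -> SnpIndex:
    """Union two indexes built on the same reference.

    On positional conflict, per-genome allele sets are unioned; if the
    unions intersect, the position is dropped and logged (conservative
    masking of sites whose alleles stopped discriminating).
    """
    if base.reference_name and additions.reference_name and (
        base.reference_name != additions.reference_name
    ):
        raise ValueError(
            f"cannot merge indexes on different references: "
            f"{base.reference_name!r} vs {additions.reference_name!r}"
        )
    merged = SnpIndex(base.reference_name or additions.reference_name, base.metadata)
    dropped = 0
    for rec in base.records():
        other = additions.get(rec.position.chrom, rec.position.pos)
        if other is None:
            merged.add(rec)
            continue
        union_A = rec.alleles_A | other.alleles_A
        union_D = rec.alleles_D | other.alleles_D
        if union_A & union_D:
            dropped += 1
            log.info(
                "merge: dropping %s:%d (unioned allele sets intersect)",
                rec.position.chrom,
                rec.position.pos + 1,
            )
            continue
        if union_A == rec.alleles_A and union_D == rec.alleles_D:
            merged.add(rec)
        else:
            merged.add(
                SnpRecord.make(
                    rec.position.chrom,
                    rec.position.pos,
                    rec.ref_base,
                    union_A,
                    union_D,
                    origin="merged",
                )
            )
    for rec in additions.records():
        if (rec.position.chrom, rec.position.pos) not in base:
            merged.add(rec)
    if dropped:
        log.warning("merge: %d conflicting positions dropped", dropped)
    merged.metadata["merged_dropped"] = dropped
    return merged


@dataclass
class IndexSummary:
    """Counts by ordered (allele_A, allele_D) pair plus type totals."""

    pair_counts: dict[tuple[str, str], int]
    n_transition: int
    n_transversion: int
    n_multi_allele: int

    @property
    def total(self) -> int:
        return self.n_transition + self.n_transversion + self.n_multi_allele

    @property
    def tr_tv_ratio(self) -> float:
        if self.n_transversion == 0:
            return math.nan
        return self.n_transition / self.n_transversion

    @property
    def transition_pct(self) -> float:
        if self.total == 0:
            return math.nan
        return 100.0 * self.n_transition / self.total


def summarize_pair_counts(
    pair_counts: dict[tuple[str, str], int], n_multi_allele: int = 0
) -> IndexSummary:
    """Summarize a histogram of single-allele (allele_A, allele_D) cells.

    Each pair is classified with :func:`classify_snp`; cells whose
    alleles coincide are rejected.
    """
    n_tr = n_tv = 0
    for (a, d), count in pair_counts.items():
        kind = classify_snp({a}, {d})
        if kind is SnpType.transition:
            n_tr += count
        else:
            n_tv += count
    return IndexSummary(dict(pair_counts), n_tr, n_tv, n_multi_allele)


def index_summary(index: SnpIndex) -> IndexSummary:
    """Tabulate an index by ordered allele pair and SNP type."""
    pair_counts: dict[tuple[str, str], int] = {}
    n_multi = 0
    for rec in index.records():
        if rec.snp_type is SnpType.multi_allele:
            n_multi += 1
        else:
            key = (next(iter(rec.alleles_A)), next(iter(rec.alleles_D)))
            pair_counts[key] = pair_counts.get(key, 0) + 1
    return summarize_pair_counts(pair_counts, n_multi)


# ---------------------------------------------------------------------------
# serialization

_HEADER_PREFIX = "#"
_COLUMNS = ("chrom", "pos", "ref", "alleles_A", "alleles_D", "snp_type")


def write_index(index: SnpIndex, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#reference={index.reference_name}\n")
        for key, value in sorted(index.metadata.items()):
            fh.write(f"#{key}={value}\n")
        fh.write("#" + "\t".join(_COLUMNS) + "\n")
        for rec in index.records():
            fh.write(
                "\t".join(
                    (
                        rec.position.chrom,
                        str(rec.position.pos + 1),
                        rec.ref_base,
                        ",".join(sorted(rec.alleles_A)),
                        ",".join(sorted(rec.alleles_D)),
                        rec.snp_type.value,
                    )
                )
                + "\n"
            )


def read_index(path) -> SnpIndex:
    index = SnpIndex()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith(_HEADER_PREFIX):
                body = line[1:]
                if "=" in body:
                    key, _, value = body.partition("=")
                    if key == "reference":
                        index.reference_name = value
                    else:
                        index.metadata[key] = _coerce(value)
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise FormatError(f"line {lineno}: expected 6 columns, got {len(fields)}")
            chrom, pos_s, ref, a_s, d_s, type_s = fields
            try:
                pos1 = int(pos_s)
            except ValueError as exc:
                raise FormatError(f"line {lineno}: bad position {pos_s!r}") from exc
            try:
                rec = SnpRecord.make(chrom, pos1 - 1, ref, a_s.split(","), d_s.split(","))
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from exc
            if rec.snp_type.value != type_s:
                raise FormatError(
                    f"line {lineno}: snp_type column {type_s!r} disagrees with "
                    f"alleles ({rec.snp_type.value})"
                )
            try:
                index.add(rec)
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from exc
    return index


def _coerce(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            continue
    return value


def export_gsnap(index: SnpIndex, path) -> int:
    """Write the index in the SNP-tolerant mapper's text dialect.

    One line per exported SNP: ``>label chrom:pos1 XY`` where X is the
    reference-matching allele and Y the alternate.  Records where no
    allele matches the reference expand into one line per alternate,
    pairing the reference base with it (and are logged); multi-allele
    records expand likewise.  Returns the number of lines written.
    """
    ordinal = 0
    with open(path, "w") as fh:
        for rec in index.records():
            chrom = rec.position.chrom
            pos1 = rec.position.pos + 1
            alleles = rec.alleles_A | rec.alleles_D
            if rec.snp_type is not SnpType.multi_allele and rec.ref_base in alleles:
                alt = next(iter(alleles - {rec.ref_base}))
                pairs = [rec.ref_base + alt]
            else:
                if rec.ref_base not in alleles:
                    log.info(
                        "export: %s:%d has no reference-matching allele; "
                        "pairing reference with each alternate",
                        chrom,
                        pos1,
                    )
                pairs = [rec.ref_base + alt for alt in sorted(alleles - {rec.ref_base})]
            for pair in pairs:
                ordinal += 1
                fh.write(f">s{ordinal} {chrom}:{pos1} {pair}\n")
    return ordinal


def write_vcf(index: SnpIndex, path) -> None:
    """Write-only VCF export; ALT carries non-reference alleles and INFO
    tags each allele with its genome of origin."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##reference={index.reference_name}\n")
        fh.write(
            '##INFO=<ID=GOA,Number=.,Type=String,Description='
            '"genome:allele pairs at this site">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, rec in enumerate(index.records(), start=1):
            alts = sorted((rec.alleles_A | rec.alleles_D) - {rec.ref_base})
            goa = ",".join(
                [f"{GENOME_A}:{b}" for b in sorted(rec.alleles_A)]
                + [f"{GENOME_D}:{b}" for b in sorted(rec.alleles_D)]
            )
            fh.write(
                "\t".join(
                    (
                        rec.position.chrom,
                        str(rec.position.pos + 1),
                        f"s{i}",
                        rec.ref_base,
                        ",".join(alts) if alts else ".",
                        ".",
                        ".",
                        f"GOA={goa}",
                    )
                )
                + "\n"
            )
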