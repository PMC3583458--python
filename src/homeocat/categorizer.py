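"""Assign aligned reads to their subgenome of origin.

Each read is genotyped at every indexed position it overlaps; the
fraction of genome-informative matches decides the category: A, D,
X (chimeric), or N (unknown).
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from dataclasses import dataclass, field
from enum import Enum

import pysam

from .formats_io import AlignedRead, GenomicPosition, aligned_read_from_pysam, read_to_reference_pairs
from .snp_index import SnpIndex

__all__ = [
    "Verdict",
    "Category",
    "SiteMatch",
    "CategoryResult",
    "CategorizerConfig",
    "genotype_read",
    "tally",
    "categorize",
    "categorize_read",
    "partition_alignment",
    "PartitionStats",
    "write_stats",
]

log = logging.getLogger(__name__)


class Verdict(str, Enum):
    matches_A = "matches_A"
    matches_D = "matches_D"
    matches_neither = "matches_neither"
    uninformative_skipped = "uninformative_skipped"
    uninformative_strand = "uninformative_strand"  # bisulfite mode only


class Category(str, Enum):
    A = "A"
    D = "D"
    X = "X"
    N = "N"


@dataclass(frozen=True)
class SiteMatch:
    position: GenomicPosition
    read_base: str
    verdict: Verdict


@dataclass(frozen=True)
class CategoryResult:
    category: Category
    n_matches_A: int
    n_matches_D: int
    n_neither: int
    n_sites_overlapped: int


@dataclass(frozen=True)
class CategorizerConfig:
    """Tunables for read categorization.

    ``threshold`` must exceed 0.5 so at most one genome can reach it.
    ``tag_*`` are the SAM auxiliary tags written to output records.
    """

    threshold: float = 0.75
    min_base_quality: int = 20
    pair_mode: str = "joint"
    tag_category: str = "YC"
    tag_a: str = "YA"
    tag_d: str = "YD"

    def __post_init__(self) -> None:
        if not (0.5 < self.threshold <= 1.0):
            raise ValueError("threshold must lie in (0.5, 1.0]")
        if self.pair_mode not in ("joint", "independent"):
            raise ValueError("pair_mode must be 'joint' or 'independent'")


def genotype_read(
    read: AlignedRead, index: SnpIndex, config: CategorizerConfig | None = None
) -> list[SiteMatch]:
    """Compare the read's bases at indexed positions to the allele sets.

    Sites under deletions or reference skips produce no SiteMatch; sites
    with base quality below the floor or an N base are recorded as
    uninformative_skipped.
    """
    config = config or CategorizerConfig()
    if not read.is_mapped:
        return []
    chrom = read.position.chrom
    pairs = read_to_reference_pairs(read)
    if not pairs:
        return []
    by_ref = {rpos: roff for roff, rpos in pairs}
    lo = pairs[0][1]
    hi = pairs[-1][1] + 1
    matches: list[SiteMatch] = []
    for pos in index.positions_in(chrom, lo, hi):
        roff = by_ref.get(pos)
        if roff is None:  # indexed position inside a deletion/skip
            continue
        base = read.seq[roff].upper()
        qual = read.quals[roff] if roff < len(read.quals) else None
        record = index.get(chrom, pos)
        if base == "N" or (qual is not None and qual < config.min_base_quality):
            verdict = Verdict.uninformative_skipped
        elif base in record.alleles_A:
            verdict = Verdict.matches_A
        elif base in record.alleles_D:
            verdict = Verdict.matches_D
        else:
            verdict = Verdict.matches_neither
        matches.append(SiteMatch(GenomicPosition(chrom, pos), base, verdict))
    return matches


def tally(matches: list[SiteMatch]) -> tuple[int, int, int]:
    a = sum(1 for m in matches if m.verdict is Verdict.matches_A)
    d = sum(1 for m in matches if m.verdict is Verdict.matches_D)
    neither = sum(1 for m in matches if m.verdict is Verdict.matches_neither)
    return a, d, neither


def categorize(
    matches: list[SiteMatch], config: CategorizerConfig | None = None
) -> CategoryResult:
    """Apply the threshold rule to a read's site matches.

    The denominator is a+d (genome-informative matches only); the
    threshold comparison is inclusive.
    """
    config = config or CategorizerConfig()
    a, d, neither = tally(matches)
    return CategoryResult(
        category=_category_from_tallies(a, d, config.threshold),
        n_matches_A=a,
        n_matches_D=d,
        n_neither=neither,
        n_sites_overlapped=len(matches),
    )


def _category_from_tallies(a: int, d: int, threshold: float) -> Category:
    if a + d == 0:
        return Category.N
    if a / (a + d) >= threshold:
        return Category.A
    if d / (a + d) >= threshold:
        return Category.D
    return Category.X


def categorize_read(
    read: AlignedRead, index: SnpIndex, config: CategorizerConfig | None = None
) -> CategoryResult:
    return categorize(genotype_read(read, index, config), config)


@dataclass
class PartitionStats:
    counts: dict = field(
        default_factory=lambda: {c: 0 for c in Category}
    )
    n_unmapped: int = 0
    n_secondary_skipped: int = 0

    @property
    def n_categorized(self) -> int:
        return sum(self.counts.values())

    def fractions(self) -> dict:
        total = self.n_categorized
        return {c: (n / total if total else 0.0) for c, n in self.counts.items()}


def partition_alignment(
    in_path,
    index: SnpIndex,
    config: CategorizerConfig | None = None,
    out_prefix: str | None = None,
    tag_only: bool = False,
    evaluate=None,
) -> PartitionStats:
    """Partition an alignment file into .A/.D/.X/.N outputs.

    Every mapped primary record lands in exactly one output; unmapped
    records go to .N; secondary/supplementary records are skipped with a
    counter.  In joint pair mode, mate tallies are summed before the
    threshold rule and both mates receive the joint category.  Input
    record order is preserved within each output.  ``evaluate`` may
    override per-read genotyping (used by the bisulfite mode); it takes
    the pysam record converted to AlignedRead and returns (a, d) tallies.
    """
    config = config or CategorizerConfig()
    stats = PartitionStats()

    mode_in = "rb" if str(in_path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(in_path), mode_in, check_sq=False) as fin:
        header = fin.header
        records = []  # (order, pysam record, a, d) kept in input order
        for aln in fin:
            if aln.is_secondary or aln.is_supplementary:
                stats.n_secondary_skipped += 1
                continue
            if aln.is_unmapped:
                records.append((aln, 0, 0, True))
                stats.n_unmapped += 1
                continue
            read = aligned_read_from_pysam(aln)
            if evaluate is not None:
                a, d = evaluate(read)
            else:
                a, d, _ = tally(genotype_read(read, index, config))
            records.append((aln, a, d, False))

    # joint pair mode: sum mate tallies by query name
    joint: dict[str, tuple[int, int]] = {}
    if config.pair_mode == "joint":
        acc: dict[str, list[int]] = OrderedDict()
        for aln, a, d, unmapped in records:
            if aln.is_paired and not unmapped:
                pair = acc.setdefault(aln.query_name, [0, 0, 0])
                pair[0] += a
                pair[1] += d
                pair[2] += 1
        joint = {name: (p[0], p[1]) for name, p in acc.items() if p[2] > 1}

    outputs = {}
    writers = {}
    if out_prefix is not None:
        ext = ".bam" if str(in_path).endswith(".bam") else ".sam"
        wmode = "wb" if ext == ".bam" else "w"
        if tag_only:
            writers["all"] = pysam.AlignmentFile(
                f"{out_prefix}.tagged{ext}", wmode, header=header
            )
        else:
            for cat in Category:
                writers[cat] = pysam.AlignmentFile(
                    f"{out_prefix}.{cat.value}{ext}", wmode, header=header
                )
        outputs = writers

    try:
        for aln, a, d, unmapped in records:
            if unmapped:
                cat = Category.N
            else:
                ja, jd = joint.get(aln.query_name, (a, d)) if (
                    config.pair_mode == "joint" and aln.is_paired
                ) else (a, d)
                cat = _category_from_tallies(ja, jd, config.threshold)
            stats.counts[cat] += 1
            if outputs:
                aln.set_tag(config.tag_category, cat.value, value_type="Z")
                aln.set_tag(config.tag_a, a, value_type="i")
                aln.set_tag(config.tag_d, d, value_type="i")
                writer = outputs["all"] if tag_only else outputs[cat]
                writer.write(aln)
    finally:
        for w in writers.values():
            w.close()

    if stats.n_categorized and stats.n_categorized % 1_000_000 == 0:
        log.info("categorized %d reads", stats.n_categorized)
    return stats


def write_stats(stats: PartitionStats, path) -> None:
    with open(path, "w") as fh:
        fh.write("category\tcount\tfraction\n")
        fracs = stats.fractions()
        for cat in Category:
            fh.write(f"{cat.value}\t{stats.counts[cat]}\t{fracs[cat]:.6f}\n")
        fh.write(f"unmapped\t{stats.n_unmapped}\t-\n")
        fh.write(f"secondary_skipped\t{stats.n_secondary_skipped}\t-\n")
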