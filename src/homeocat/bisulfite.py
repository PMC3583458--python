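"""Bisulfite-aware categorization and per-genome methylation reporting.

Bisulfite conversion reads out as C->T on plus-strand reads and G->A on
minus-strand reads.  The strand of each read is inferred from those two
mismatch counts; matching at indexed sites is then conversion-tolerant
and strand-conditional: a C/T allele pair cannot be scored on a
plus-strand read, nor G/A on a minus-strand read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import pysam

from .categorizer import (
    Category,
    CategorizerConfig,
    CategoryResult,
    SiteMatch,
    Verdict,
    categorize,
)
from .formats_io import AlignedRead, GenomicPosition, aligned_read_from_pysam, read_to_reference_pairs
from .snp_index import SnpIndex, SnpRecord

__all__ = [
    "Strand",
    "StrandCall",
    "infer_strand",
    "bs_match",
    "genotype_bs_read",
    "evaluate_bs_read",
    "methylation_context",
    "MethylSiteReport",
    "methylation_report",
    "write_methylation_report",
]

log = logging.getLogger(__name__)


class Strand(str, Enum):
    plus = "+"
    minus = "-"
    ambiguous = "ambiguous"


@dataclass(frozen=True)
class StrandCall:
    strand: Strand
    n_ct: int
    n_ga: int


def infer_strand(
    read: AlignedRead,
    reference: dict[str, str],
    index: SnpIndex | None = None,
) -> StrandCall:
    """Infer the bisulfite origin strand from conversion-type mismatches.

    Counts aligned columns where reference C reads as T (n_ct) and
    reference G reads as A (n_ga).  More C->T means plus strand, more
    G->A means minus, ties (including 0/0) are ambiguous.  Indexed SNP
    positions are excluded: a C/T homoeo-SNP is not conversion evidence.
    """
    n_ct = n_ga = 0
    if read.is_mapped:
        chrom = read.position.chrom
        ref_seq = reference[chrom]
        for roff, rpos in read_to_reference_pairs(read):
            if index is not None and (chrom, rpos) in index:
                continue
            ref_base = ref_seq[rpos]
            base = read.seq[roff]
            if ref_base == "C" and base == "T":
                n_ct += 1
            elif ref_base == "G" and base == "A":
                n_ga += 1
    if n_ct > n_ga:
        return StrandCall(Strand.plus, n_ct, n_ga)
    if n_ga > n_ct:
        return StrandCall(Strand.minus, n_ct, n_ga)
    return StrandCall(Strand.ambiguous, n_ct, n_ga)


def _strand_confounded(record: SnpRecord, strand: Strand) -> bool:
    """True when the allele pair cannot be scored on this strand.

    Plus strand: conversion mimics a C->T difference, so any C in one
    genome paired against a T in the other is confounded.  Minus strand:
    likewise for G against A.  Extended set-wise for multi-allele
    records.
    """
    if strand is Strand.plus:
        hot, cold = "C", "T"
    else:
        hot, cold = "G", "A"
    return (hot in record.alleles_A and cold in record.alleles_D) or (
        cold in record.alleles_A and hot in record.alleles_D
    )


def bs_match(read_base: str, record: SnpRecord, strand: Strand) -> Verdict:
    """Conversion-tolerant, strand-conditional allele matching.

    On the plus strand a read T additionally matches a C allele; on the
    minus strand a read A additionally matches a G allele.  Exact base
    equality always matches.  Strand-confounded allele pairs return
    uninformative_strand before any matching.
    """
    if strand not in (Strand.plus, Strand.minus):
        raise ValueError("bs_match requires a resolved strand (plus or minus)")
    if _strand_confounded(record, strand):
        return Verdict.uninformative_strand
    base = read_base.upper()

    def hits(alleles) -> bool:
        if base in alleles:
            return True
        if strand is Strand.plus and base == "T" and "C" in alleles:
            return True
        if strand is Strand.minus and base == "A" and "G" in alleles:
            return True
        return False

    in_a = hits(record.alleles_A)
    in_d = hits(record.alleles_D)
    if in_a and in_d:
        # cannot happen for non-confounded records, guarded for safety
        return Verdict.uninformative_strand
    if in_a:
        return Verdict.matches_A
    if in_d:
        return Verdict.matches_D
    return Verdict.matches_neither


def genotype_bs_read(
    read: AlignedRead,
    index: SnpIndex,
    reference: dict[str, str],
    config: CategorizerConfig | None = None,
    strand_call: StrandCall | None = None,
) -> tuple[StrandCall, list[SiteMatch]]:
    """Strand-aware genotyping of a bisulfite read at indexed sites.

    For ambiguous-strand reads each site is evaluated under both strand
    hypotheses and kept only when they agree; disagreeing sites are
    recorded as uninformative_strand.
    """
    config = config or CategorizerConfig()
    if strand_call is None:
        strand_call = infer_strand(read, reference, index)
    if not read.is_mapped:
        return strand_call, []
    chrom = read.position.chrom
    pairs = read_to_reference_pairs(read)
    if not pairs:
        return strand_call, []
    by_ref = {rpos: roff for roff, rpos in pairs}
    matches: list[SiteMatch] = []
    for pos in index.positions_in(chrom, pairs[0][1], pairs[-1][1] + 1):
        roff = by_ref.get(pos)
        if roff is None:
            continue
        base = read.seq[roff].upper()
        qual = read.quals[roff] if roff < len(read.quals) else None
        record = index.get(chrom, pos)
        if base == "N" or (qual is not None and qual < config.min_base_quality):
            verdict = Verdict.uninformative_skipped
        elif strand_call.strand is Strand.ambiguous:
            v_plus = bs_match(base, record, Strand.plus)
            v_minus = bs_match(base, record, Strand.minus)
            verdict = v_plus if v_plus is v_minus else Verdict.uninformative_strand
        else:
            verdict = bs_match(base, record, strand_call.strand)
        matches.append(SiteMatch(GenomicPosition(chrom, pos), base, verdict))
    return strand_call, matches


def evaluate_bs_read(
    read: AlignedRead,
    index: SnpIndex,
    reference: dict[str, str],
    config: CategorizerConfig | None = None,
) -> CategoryResult:
    config = config or CategorizerConfig()
    _, matches = genotype_bs_read(read, index, reference, config)
    return categorize(matches, config)


def methylation_context(seq: str, pos: int, strand: Strand) -> str:
    """Trinucleotide methylation context (CG/CHG/CHH) of a cytosine.

    ``strand`` plus means the reference base at ``pos`` is C; minus
    means G (a cytosine on the reverse strand, so context is read
    upstream on the reverse complement).  Returns "NA" when the contig
    end or an N base leaves the context unresolvable.
    """
    base = seq[pos]
    if strand is Strand.plus:
        if base != "C":
            raise ValueError(f"position {pos} is {base}, not C, on the plus strand")
        b1 = seq[pos + 1] if pos + 1 < len(seq) else None
        b2 = seq[pos + 2] if pos + 2 < len(seq) else None
        return _context_from_downstream(b1, b2, "G")
    if strand is Strand.minus:
        if base != "G":
            raise ValueError(f"position {pos} is {base}, not G, on the minus strand")
        b1 = seq[pos - 1] if pos - 1 >= 0 else None
        b2 = seq[pos - 2] if pos - 2 >= 0 else None
        return _context_from_downstream(b1, b2, "C")
    raise ValueError("methylation context requires a resolved strand")


def _context_from_downstream(b1: str | None, b2: str | None, g: str) -> str:
    # g is the strand-appropriate guanine partner ('G' plus, 'C' minus);
    # H is any concrete base that is not g.
    if b1 is None or b1 == "N":
        return "NA"
    if b1 == g:
        return "CG"
    if b2 is None or b2 == "N":
        return "NA"
    if b2 == g:
        return "CHG"
    return "CHH"


@dataclass
class MethylSiteReport:
    """Converted/unconverted tallies at one reference C (plus) or G
    (minus) position, in total and per read category.

    Counts are floats because ambiguous-strand reads contribute half a
    read to each strand.
    """

    position: GenomicPosition
    strand: Strand
    context: str
    per_category: dict = field(
        default_factory=lambda: {c: [0.0, 0.0] for c in Category}
    )  # category -> [unconverted, converted]

    @property
    def unconverted(self) -> float:
        return sum(v[0] for v in self.per_category.values())

    @property
    def converted(self) -> float:
        return sum(v[1] for v in self.per_category.values())

    @property
    def level(self) -> float:
        total = self.unconverted + self.converted
        return self.unconverted / total if total else float("nan")


def methylation_report(
    in_path,
    reference: dict[str, str],
    index: SnpIndex,
    config: CategorizerConfig | None = None,
) -> list[MethylSiteReport]:
    """Tally methylation evidence at every covered reference C/G position.

    Reads contribute only to sites on their inferred strand; ambiguous
    reads contribute 0.5 weight to both strands.  Per-category columns
    come from the categorization tag when present, otherwise the read is
    categorized inline in bisulfite mode.
    """
    config = config or CategorizerConfig()
    sites: dict[tuple[str, int, Strand], MethylSiteReport] = {}

    mode_in = "rb" if str(in_path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(in_path), mode_in, check_sq=False) as fin:
        for aln in fin:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            read = aligned_read_from_pysam(aln)
            strand_call = infer_strand(read, reference, index)
            if aln.has_tag(config.tag_category):
                category = Category(aln.get_tag(config.tag_category))
            else:
                _, matches = genotype_bs_read(
                    read, index, reference, config, strand_call
                )
                category = categorize(matches, config).category
            _accumulate_read(sites, read, strand_call.strand, category, reference)

    out = sorted(
        sites.values(), key=lambda s: (s.position.chrom, s.position.pos, s.strand.value)
    )
    for site in out:
        site.context = methylation_context(
            reference[site.position.chrom], site.position.pos, site.strand
        )
    return out


def _accumulate_read(sites, read, strand, category, reference) -> None:
    chrom = read.position.chrom
    ref_seq = reference[chrom]
    if strand is Strand.ambiguous:
        contributions = ((Strand.plus, 0.5), (Strand.minus, 0.5))
    else:
        contributions = ((strand, 1.0),)
    for roff, rpos in read_to_reference_pairs(read):
        ref_base = ref_seq[rpos]
        base = read.seq[roff]
        for site_strand, weight in contributions:
            if site_strand is Strand.plus and ref_base == "C":
                unconverted, converted = base == "C", base == "T"
            elif site_strand is Strand.minus and ref_base == "G":
                unconverted, converted = base == "G", base == "A"
            else:
                continue
            if not (unconverted or converted):
                continue
            key = (chrom, rpos, site_strand)
            site = sites.get(key)
            if site is None:
                site = sites[key] = MethylSiteReport(
                    GenomicPosition(chrom, rpos), site_strand, context="NA"
                )
            site.per_category[category][0 if unconverted else 1] += weight


def write_methylation_report(
    report: list[MethylSiteReport], path, params: dict | None = None
) -> None:
    """Tab-delimited report; counts serialized with one decimal place
    (half-read weighting makes them rational with denominator 2)."""
    cats = list(Category)
    with open(path, "w") as fh:
        if params:
            fh.write("#" + " ".join(f"{k}={v}" for k, v in sorted(params.items())) + "\n")
        cols = ["chrom", "pos", "strand", "context", "total_unconverted", "total_converted"]
        for c in cats:
            cols += [f"{c.value}_unconverted", f"{c.value}_converted"]
        fh.write("\t".join(cols) + "\n")
        for site in report:
            row = [
                site.position.chrom,
                str(site.position.pos + 1),
                site.strand.value,
                site.context,
                f"{site.unconverted:.1f}",
                f"{site.converted:.1f}",
            ]
            for c in cats:
                u, v = site.per_category[c]
                row += [f"{u:.1f}", f"{v:.1f}"]
            fh.write("\t".join(row) + "\n")
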