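"""Index-level genomic statistics.

SNP density per chromosome/window/gene, per-gene SNP count histograms,
and the theoretical categorizability fraction: the share of read start
positions from which a read of a given length overlaps at least one
indexed SNP.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import gffutils

from .snp_index import SnpIndex

__all__ = [
    "Region",
    "DensityRow",
    "CategorizabilityResult",
    "chromosome_regions",
    "window_regions",
    "snp_density",
    "GeneSnpCounts",
    "per_gene_snp_counts",
    "categorizable_fraction",
]


@dataclass(frozen=True)
class Region:
    """A named half-open interval [start, end) on a chromosome."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"zero- or negative-length region {self.name}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class DensityRow:
    region: str
    length_bp: int
    n_snps: int

    @property
    def density(self) -> float:
        """SNPs per kbp."""
        return self.n_snps / (self.length_bp / 1000)


def chromosome_regions(genome_lengths: dict[str, int]) -> list[Region]:
    return [Region(c, c, 0, n) for c, n in sorted(genome_lengths.items())]


def window_regions(genome_lengths: dict[str, int], width: int) -> list[Region]:
    if width < 1:
        raise ValueError("window width must be >= 1")
    out = []
    for chrom, n in sorted(genome_lengths.items()):
        for start in range(0, n, width):
            end = min(start + width, n)
            out.append(Region(f"{chrom}:{start + 1}-{end}", chrom, start, end))
    return out


def snp_density(index: SnpIndex, regions: list[Region]) -> list[DensityRow]:
    """Per-region SNP counts and densities, with a genome-wide summary row."""
    rows = [
        DensityRow(r.name, r.length, len(index.positions_in(r.chrom, r.start, r.end)))
        for r in regions
    ]
    total_len = sum(r.length_bp for r in rows)
    total_snps = sum(r.n_snps for r in rows)
    rows.append(DensityRow("TOTAL", total_len, total_snps))
    return rows


@dataclass
class GeneSnpCounts:
    per_gene: dict[str, int]
    per_gene_exonic: dict[str, int]
    zero_snp_genes: list[str]

    def histogram(self, bin_width: int = 10) -> Counter:
        """Counter mapping bin start (0, bin_width, ...) to gene count."""
        hist: Counter = Counter()
        for n in self.per_gene.values():
            hist[(n // bin_width) * bin_width] += 1
        return hist


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def per_gene_snp_counts(index: SnpIndex, gff3_path) -> GeneSnpCounts:
    """Count indexed SNPs per gene span and per merged exon union.

    A SNP inside two overlapping genes increments both; exon unions are
    merged per gene so no SNP is double-counted within one gene.
    """
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    per_gene: dict[str, int] = {}
    per_exonic: dict[str, int] = {}
    zero: list[str] = []
    for gene in db.features_of_type("gene"):
        gid = gene.id
        # GFF3 is 1-based closed; convert to 0-based half-open
        count = len(index.positions_in(gene.seqid, gene.start - 1, gene.end))
        per_gene[gid] = count
        exon_iv = [
            (ex.start - 1, ex.end)
            for ex in db.children(gene, featuretype="exon")
        ]
        per_exonic[gid] = sum(
            len(index.positions_in(gene.seqid, s, e))
            for s, e in _merge_intervals(exon_iv)
        )
        if count == 0:
            zero.append(gid)
    return GeneSnpCounts(per_gene, per_exonic, zero)


@dataclass(frozen=True)
class CategorizabilityResult:
    read_length_bp: int
    covered_bp: int
    genome_bp: int

    @property
    def fraction(self) -> float:
        return self.covered_bp / self.genome_bp if self.genome_bp else 0.0


def categorizable_fraction(
    index: SnpIndex,
    read_length: int,
    genome_lengths: dict[str, int],
    regions: list[Region] | None = None,
) -> CategorizabilityResult:
    """Fraction of read start positions that would overlap >= 1 SNP.

    A 0-based start s is covered iff some indexed position p satisfies
    s <= p <= s + read_length - 1, i.e. s lies in [p - read_length + 1, p]
    clipped to the chromosome.  Computed exactly by interval merging;
    optionally restricted to a region set.
    """
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    restrict: dict[str, list[tuple[int, int]]] = {}
    if regions is not None:
        for r in regions:
            restrict.setdefault(r.chrom, []).append((r.start, r.end))
        restrict = {c: _merge_intervals(iv) for c, iv in restrict.items()}

    covered = 0
    genome = 0
    for chrom, length in genome_lengths.items():
        if regions is None:
            windows = [(0, length)]
        else:
            windows = restrict.get(chrom, [])
        genome += sum(min(e, length) - s for s, e in windows)
        spans = [
            (max(0, p - read_length + 1), min(p + 1, length))
            for p in index.positions_in(chrom, 0, length)
        ]
        for s, e in _merge_intervals(spans):
            for ws, we in windows:
                lo, hi = max(s, ws), min(e, we, length)
                if hi > lo:
                    covered += hi - lo
    return CategorizabilityResult(read_length, covered, genome)
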