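"""Synthetic-data generator: diverged genome pairs, labelled read sets,
bisulfite conversion, and per-genome pileups.

All randomness flows through one integer-seeded numpy generator, so a
fixed seed reproduces every output byte-for-byte across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pysam

from .bisulfite import Strand, methylation_context
from .formats_io import AlignedRead, GenomicPosition
from .snp_index import GENOME_A, GENOME_D, SnpIndex, SnpRecord

__all__ = [
    "SimConfig",
    "TruthSnp",
    "SimGenomes",
    "SimRead",
    "MethTruth",
    "simulate_genomes",
    "truth_index",
    "simulate_reads",
    "bisulfite_convert",
    "make_pileups",
    "write_pileups",
    "write_fasta",
    "write_sam",
    "write_fastq",
    "write_truth_snps",
    "write_truth_reads",
]

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class SimConfig:
    genome_length: int = 10_000
    n_chroms: int = 1
    snp_density: float = 3.5  # SNPs per kbp
    trtv_ratio: float = 1.5
    read_length: int = 100
    depth: float = 10.0
    error_rate: float = 0.0
    indel_rate: float = 0.0  # per-read probability of one small indel
    proportion_A: float = 0.5
    base_quality: int = 35
    conversion_rate: float = 1.0
    methylation: dict = field(
        default_factory=lambda: {"CG": 0.8, "CHG": 0.5, "CHH": 0.1}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("error_rate", "indel_rate", "proportion_A", "conversion_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class TruthSnp:
    chrom: str
    pos: int  # 0-based
    base_D: str  # equals the reference base
    base_A: str


@dataclass
class SimGenomes:
    reference: dict[str, str]  # genome D, the mapping reference
    genome_A: dict[str, str]
    truth_snps: list[TruthSnp]

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.reference.items()}


@dataclass
class SimRead:
    name: str
    chrom: str
    start: int  # 0-based leftmost reference position
    cigar: tuple[tuple[str, int], ...]
    seq: str
    genome: str  # true genome label, A or D
    bs_strand: str | None = None  # '+', '-', or None for untreated reads
    base_quality: int = 35

    def to_aligned_read(self) -> AlignedRead:
        return AlignedRead(
            name=self.name,
            position=GenomicPosition(self.chrom, self.start),
            cigar=self.cigar,
            seq=self.seq,
            quals=tuple([self.base_quality] * len(self.seq)),
            flag=0,
        )


@dataclass(frozen=True)
class MethTruth:
    read_name: str
    chrom: str
    pos: int
    strand: str
    context: str
    methylated: bool


def _chrom_names(n: int) -> list[str]:
    # zero-padded so lexicographic order equals numeric order
    width = len(str(n))
    return [f"chr{str(i + 1).zfill(width)}" for i in range(n)]


def simulate_genomes(config: SimConfig, rng: np.random.Generator | None = None) -> SimGenomes:
    """Draw genome D uniformly and derive genome A by substitution.

    Substitutions are placed uniformly without collision at the target
    density; each is a transition with probability r/(r+1) where r is
    the target transition/transversion ratio.
    """
    rng = rng or np.random.default_rng(config.seed)
    reference: dict[str, str] = {}
    genome_A: dict[str, str] = {}
    truth: list[TruthSnp] = []
    p_transition = config.trtv_ratio / (config.trtv_ratio + 1.0)
    for chrom in _chrom_names(config.n_chroms):
        length = config.genome_length
        seq_d = "".join(_BASES[rng.integers(0, 4, size=length)])
        n_snps = int(round(config.snp_density * length / 1000))
        if n_snps > length:
            raise ValueError(
                f"snp_density {config.snp_density}/kbp needs {n_snps} sites "
                f"but {chrom} has only {length} bp"
            )
        positions = np.sort(rng.choice(length, size=n_snps, replace=False))
        seq_a = list(seq_d)
        for pos in positions:
            ref = seq_d[pos]
            if rng.random() < p_transition:
                alt = _TRANSITION[ref]
            else:
                alt = _TRANSVERSIONS[ref][rng.integers(0, 2)]
            seq_a[pos] = alt
            truth.append(TruthSnp(chrom, int(pos), ref, alt))
        reference[chrom] = seq_d
        genome_A[chrom] = "".join(seq_a)
    return SimGenomes(reference, genome_A, truth)


def truth_index(genomes: SimGenomes, reference_name: str = "sim") -> SnpIndex:
    """The truth SNP table as a ready-to-use index (A allele vs D allele)."""
    index = SnpIndex(reference_name)
    for snp in genomes.truth_snps:
        index.add(
            SnpRecord.make(snp.chrom, snp.pos, snp.base_D, {snp.base_A}, {snp.base_D})
        )
    return index


def simulate_reads(
    genomes: SimGenomes,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[SimRead]:
    """Sample reads from both genomes, pre-aligned at true coordinates.

    Reads are emitted on the forward alignment strand with simple CIGARs
    (optionally one small insertion or deletion per read when
    indel_rate > 0), then hit by uniform substitution errors.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    chroms = list(genomes.reference)
    lengths = np.array([len(genomes.reference[c]) for c in chroms], dtype=float)
    total = lengths.sum()
    n_reads = int(round(config.depth * total / config.read_length))
    chrom_p = lengths / total
    reads: list[SimRead] = []
    max_del = 3
    for i in range(n_reads):
        genome = GENOME_A if rng.random() < config.proportion_A else GENOME_D
        ci = rng.choice(len(chroms), p=chrom_p)
        chrom = chroms[ci]
        src = genomes.genome_A[chrom] if genome == GENOME_A else genomes.reference[chrom]
        L = config.read_length
        span_max = len(src) - L - max_del
        if span_max < 1:
            raise ValueError(f"{chrom} too short for read length {L}")
        start = int(rng.integers(0, span_max))
        if config.indel_rate > 0 and rng.random() < config.indel_rate and L >= 6:
            k = int(rng.integers(1, max_del + 1))
            if rng.random() < 0.5:  # insertion
                a = int(rng.integers(1, L - k))
                ins = "".join(_BASES[rng.integers(0, 4, size=k)])
                seq = src[start : start + a] + ins + src[start + a : start + L - k]
                cigar = (("M", a), ("I", k), ("M", L - a - k))
            else:  # deletion
                a = int(rng.integers(1, L))
                seq = src[start : start + a] + src[start + a + k : start + a + k + L - a]
                cigar = (("M", a), ("D", k), ("M", L - a))
        else:
            seq = src[start : start + L]
            cigar = (("M", L),)
        if config.error_rate > 0:
            seq = _apply_errors(seq, config.error_rate, rng)
        reads.append(
            SimRead(
                name=f"sim_{genome}_{i:06d}",
                chrom=chrom,
                start=start,
                cigar=cigar,
                seq=seq,
                genome=genome,
                base_quality=config.base_quality,
            )
        )
    return reads


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1")
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    if len(hits) == 0:
        return seq
    out = list(seq)
    for i in hits:
        others = [b for b in "ACGT" if b != seq[i]]
        out[i] = others[rng.integers(0, 3)]
    return "".join(out)


def bisulfite_convert(
    reads: list[SimRead],
    genomes: SimGenomes,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[SimRead], list[MethTruth]]:
    """Assign each read a bisulfite origin strand and convert it.

    Plus-strand reads: each cytosine of the source molecule is
    methylated with its context probability; unmethylated cytosines read
    out as T with probability conversion_rate.  Minus-strand reads: the
    symmetric G->A conversion.  Context is taken from the source genome.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    out: list[SimRead] = []
    truth: list[MethTruth] = []
    for read in reads:
        src = (
            genomes.genome_A[read.chrom]
            if read.genome == GENOME_A
            else genomes.reference[read.chrom]
        )
        strand = "+" if rng.random() < 0.5 else "-"
        target, converted_to = ("C", "T") if strand == "+" else ("G", "A")
        strand_enum = Strand.plus if strand == "+" else Strand.minus
        seq = list(read.seq)
        roff = 0
        rpos = read.start
        for op, length in read.cigar:
            if op in "M=X":
                for k in range(length):
                    pos = rpos + k
                    if src[pos] == target and seq[roff + k] == target:
                        context = methylation_context(src, pos, strand_enum)
                        p_meth = config.methylation.get(context, 0.0)
                        methylated = bool(rng.random() < p_meth)
                        if not methylated and rng.random() < config.conversion_rate:
                            seq[roff + k] = converted_to
                        truth.append(
                            MethTruth(read.name, read.chrom, pos, strand, context, methylated)
                        )
                roff += length
                rpos += length
            elif op in "IS":
                roff += length
            elif op in "DN":
                rpos += length
        out.append(replace(read, seq="".join(seq), bs_strand=strand))
    return out, truth


def make_pileups(
    reads: list[SimRead], reference: dict[str, str]
) -> dict[str, list[str]]:
    """Per-genome pileup text lines in the 6-column samtools dialect.

    Reads are partitioned by their true genome label; '.' marks a
    reference-matching base (all simulated reads align forward).
    """
    counts: dict[str, dict[tuple[str, int], list[str]]] = {GENOME_A: {}, GENOME_D: {}}
    for read in reads:
        bucket = counts[read.genome]
        roff = 0
        rpos = read.start
        for op, length in read.cigar:
            if op in "M=X":
                for k in range(length):
                    bucket.setdefault((read.chrom, rpos + k), []).append(
                        read.seq[roff + k]
                    )
                roff += length
                rpos += length
            elif op in "IS":
                roff += length
            elif op in "DN":
                rpos += length
    out: dict[str, list[str]] = {}
    for genome, bucket in counts.items():
        lines = []
        for (chrom, pos), bases in sorted(bucket.items()):
            ref = reference[chrom][pos]
            column = "".join("." if b == ref else b for b in bases)
            lines.append(
                f"{chrom}\t{pos + 1}\t{ref}\t{len(bases)}\t{column}\t{'I' * len(bases)}"
            )
        out[genome] = lines
    return out


def write_pileups(pileups: dict[str, list[str]], prefix) -> dict[str, str]:
    paths = {}
    for genome, lines in pileups.items():
        path = f"{prefix}.{genome}.pileup"
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + ("\n" if lines else ""))
        paths[genome] = path
    return paths


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            seq = seqs[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_sam(reads: list[SimRead], genome_lengths: dict[str, int], path) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": n} for c, n in sorted(genome_lengths.items())],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        tid = {c: i for i, (c, _) in enumerate(sorted(genome_lengths.items()))}
        for read in reads:
            aln = pysam.AlignedSegment(fh.header)
            aln.query_name = read.name
            aln.query_sequence = read.seq
            aln.flag = 0
            aln.reference_id = tid[read.chrom]
            aln.reference_start = read.start
            aln.mapping_quality = 60
            aln.cigarstring = "".join(f"{n}{op}" for op, n in read.cigar)
            aln.query_qualities = pysam.qualitystring_to_array(
                chr(read.base_quality + 33) * len(read.seq)
            )
            aln.set_tag("YG", read.genome, value_type="Z")
            if read.bs_strand:
                aln.set_tag("YS", read.bs_strand, value_type="Z")
            fh.write(aln)


def write_fastq(reads: list[SimRead], path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(
                f"@{read.name}\n{read.seq}\n+\n"
                f"{chr(read.base_quality + 33) * len(read.seq)}\n"
            )


def write_truth_snps(truth: list[TruthSnp], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tbase_D\tbase_A\n")
        for snp in truth:
            fh.write(f"{snp.chrom}\t{snp.pos + 1}\t{snp.base_D}\t{snp.base_A}\n")


def write_truth_reads(reads: list[SimRead], path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tgenome\tchrom\tstart\tbs_strand\n")
        for read in reads:
            fh.write(
                f"{read.name}\t{read.genome}\t{read.chrom}\t{read.start + 1}\t"
                f"{read.bs_strand or '.'}\n"
            )
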