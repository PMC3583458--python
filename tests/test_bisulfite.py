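import math

import pytest

from homeocat.bisulfite import (
    MethylSiteReport,
    Strand,
    bs_match,
    evaluate_bs_read,
    genotype_bs_read,
    infer_strand,
    methylation_context,
    methylation_report,
    write_methylation_report,
)
from homeocat.categorizer import Category, CategorizerConfig, Verdict, genotype_read
from homeocat.simulator import (
    SimConfig,
    bisulfite_convert,
    simulate_genomes,
    simulate_reads,
    truth_index,
    write_sam,
)
from homeocat.snp_index import SnpRecord

from conftest import make_index, make_read


def record(ref="A", a="C", d="T", pos=10):
    return SnpRecord.make("chr1", pos, ref, a.split(","), d.split(","))


class TestInferStrand:
    def test_ct_mismatches_mean_plus(self):
        ref = {"chr1": "CCCAA"}
        read = make_read(pos=0, seq="TTTAA")
        call = infer_strand(read, ref)
        assert call.strand is Strand.plus
        assert (call.n_ct, call.n_ga) == (3, 0)

    def test_ga_mismatches_mean_minus(self):
        ref = {"chr1": "GGAAA"}
        read = make_read(pos=0, seq="AAAAA")
        call = infer_strand(read, ref)
        assert call.strand is Strand.minus
        assert (call.n_ct, call.n_ga) == (0, 2)

    def test_tie_is_ambiguous(self):
        ref = {"chr1": "CGAA"}
        read = make_read(pos=0, seq="TAAA")
        assert infer_strand(read, ref).strand is Strand.ambiguous

    def test_zero_zero_is_ambiguous(self):
        ref = {"chr1": "AAAA"}
        read = make_read(pos=0, seq="AAAA")
        call = infer_strand(read, ref)
        assert call.strand is Strand.ambiguous
        assert (call.n_ct, call.n_ga) == (0, 0)

    def test_indexed_positions_excluded(self):
        # the C->T at indexed position 0 is a homoeo-SNP, not conversion
        ref = {"chr1": "CGGAA"}
        index = make_index([("chr1", 0, "C", "T", "C")])
        read = make_read(pos=0, seq="TAGAA")
        call = infer_strand(read, ref, index)
        assert (call.n_ct, call.n_ga) == (0, 1)
        assert call.strand is Strand.minus


class TestBsMatch:
    """The three worked verdicts of the strand-conditional matching rule."""

    def test_ct_snp_plus_strand_t_uninformative(self):
        assert (
            bs_match("T", record(a="C", d="T"), Strand.plus)
            is Verdict.uninformative_strand
        )

    def test_ct_snp_minus_strand_t_matches_d(self):
        assert bs_match("T", record(a="C", d="T"), Strand.minus) is Verdict.matches_D

    def test_gt_snp_minus_strand_a_matches_a(self):
        assert bs_match("A", record(a="G", d="T"), Strand.minus) is Verdict.matches_A

    def test_exact_match_always_accepted(self):
        assert bs_match("G", record(a="G", d="T"), Strand.plus) is Verdict.matches_A
        assert bs_match("T", record(a="G", d="T"), Strand.plus) is Verdict.matches_D

    def test_plus_strand_t_tolerated_for_c_allele(self):
        assert bs_match("T", record(a="C", d="A"), Strand.plus) is Verdict.matches_A

    def test_minus_strand_a_tolerated_for_g_allele(self):
        assert bs_match("A", record(a="G", d="C"), Strand.minus) is Verdict.matches_A

    def test_neither(self):
        assert bs_match("G", record(a="C", d="A"), Strand.plus) is Verdict.matches_neither

    def test_ga_snp_minus_strand_uninformative(self):
        assert (
            bs_match("A", record(a="G", d="A"), Strand.minus)
            is Verdict.uninformative_strand
        )

    def test_multi_allele_confounded_setwise(self):
        rec = record(a="C,G", d="T")
        assert bs_match("G", rec, Strand.plus) is Verdict.uninformative_strand
        assert bs_match("G", rec, Strand.minus) is Verdict.matches_A

    def test_ambiguous_strand_rejected(self):
        with pytest.raises(ValueError):
            bs_match("T", record(), Strand.ambiguous)


class TestEvaluateBsRead:
    def test_transversion_sites_unaffected_by_strand(self):
        # A-genome read over a transversion SNP categorizes as A whatever
        # the conversion status
        index = make_index([("chr1", 2, "T", "G", "T")])
        ref = {"chr1": "CCGCC"}
        for seq in ("TTGTT", "CCGCC"):  # fully converted / fully methylated
            read = make_read(pos=0, seq=seq)
            assert evaluate_bs_read(read, index, ref).category is Category.A

    def test_ambiguous_read_ct_snp_dropped(self):
        # unconverted read (no conversion evidence -> ambiguous strand)
        # over one C/T SNP with base C: the plus hypothesis says
        # uninformative, the minus hypothesis says matches_A ->
        # disagreement -> site dropped -> N
        index = make_index([("chr1", 1, "C", "C", "T")])
        ref = {"chr1": "ACAAA"}
        read = make_read(pos=0, seq="ACAAA")
        strand_call, matches = genotype_bs_read(read, index, ref)
        assert strand_call.strand is Strand.ambiguous
        assert [m.verdict for m in matches] == [Verdict.uninformative_strand]
        assert evaluate_bs_read(read, index, ref).category is Category.N

    def test_minus_strand_ga_dropped_transversion_decides(self):
        # minus-strand read: {G,A} site uninformative, transversion decides
        index = make_index(
            [("chr1", 1, "G", "G", "A"), ("chr1", 5, "T", "C", "T")]
        )
        #          0123456789
        ref = {"chr1": "AGGGGTGGGG"}
        # read from A genome, minus strand, partially converted: G->A at
        # non-indexed positions 2,3 give conversion evidence
        read = make_read(pos=0, seq="AGAAGCGGGG")
        strand_call, matches = genotype_bs_read(read, index, ref)
        assert strand_call.strand is Strand.minus
        verdicts = {m.position.pos: m.verdict for m in matches}
        assert verdicts[1] is Verdict.uninformative_strand
        assert verdicts[5] is Verdict.matches_A
        assert evaluate_bs_read(read, index, ref).category is Category.A

    def test_low_quality_site_skipped(self):
        index = make_index([("chr1", 0, "T", "G", "T")])
        ref = {"chr1": "TAAA"}
        read = make_read(pos=0, seq="GAAA", quals=[5, 35, 35, 35])
        _, matches = genotype_bs_read(read, index, ref)
        assert matches[0].verdict is Verdict.uninformative_skipped


class TestMethylationContext:
    def test_cg(self):
        assert methylation_context("ACGTT", 1, Strand.plus) == "CG"

    def test_chg(self):
        assert methylation_context("ACAGT", 1, Strand.plus) == "CHG"

    def test_chh(self):
        assert methylation_context("ACATT", 1, Strand.plus) == "CHH"

    def test_minus_strand_cg(self):
        # CG on the reverse complement: ...CG...
        assert methylation_context("ACGTT", 2, Strand.minus) == "CG"

    def test_minus_strand_chg(self):
        # C-T-G: reverse complement of G at 3 reads C,A -> CHG
        assert methylation_context("ACTGT", 3, Strand.minus) == "CHG"

    def test_minus_strand_chh(self):
        assert methylation_context("ATTGT", 3, Strand.minus) == "CHH"

    def test_contig_edge_na(self):
        assert methylation_context("AC", 1, Strand.plus) == "NA"
        assert methylation_context("ACT", 1, Strand.plus) == "NA"  # CHG vs CHH unresolvable
        assert methylation_context("GT", 0, Strand.minus) == "NA"

    def test_edge_resolvable_cg(self):
        # one downstream base is enough when it is G
        assert methylation_context("ACG", 1, Strand.plus) == "CG"

    def test_wrong_base_rejected(self):
        with pytest.raises(ValueError):
            methylation_context("AAAA", 1, Strand.plus)
        with pytest.raises(ValueError):
            methylation_context("AAAA", 1, Strand.minus)


class TestSubsetProperty:
    def test_bs_informative_sites_subset_of_standard(self):
        # on any read, sites usable in BS mode are a subset of the sites
        # usable in standard mode; hence BS-mode N fraction can only grow
        config = SimConfig(
            genome_length=15_000, depth=2.0, seed=3, snp_density=6.0
        )
        genomes = simulate_genomes(config)
        reads = simulate_reads(genomes, config)
        bs_reads, _ = bisulfite_convert(reads, genomes, config)
        index = truth_index(genomes)
        cat_config = CategorizerConfig()
        informative = (Verdict.matches_A, Verdict.matches_D)
        n_std_n = n_bs_n = 0
        for plain, converted in zip(reads, bs_reads):
            aligned = plain.to_aligned_read()
            std_sites = {
                m.position.pos
                for m in genotype_read(aligned, index, cat_config)
                if m.verdict in informative
            }
            _, bs_matches = genotype_bs_read(
                converted.to_aligned_read(), index, genomes.reference, cat_config
            )
            bs_sites = {
                m.position.pos for m in bs_matches if m.verdict in informative
            }
            assert bs_sites <= std_sites
            n_std_n += not std_sites
            n_bs_n += not bs_sites
        assert n_bs_n >= n_std_n

    def test_unconverted_transversion_only_equals_standard(self):
        # restrict the index to transversion SNPs; on unconverted
        # error-free reads, BS-mode categories equal standard mode
        config = SimConfig(
            genome_length=15_000,
            depth=2.0,
            seed=5,
            snp_density=6.0,
            trtv_ratio=0.0,  # transversions only
            methylation={"CG": 1.0, "CHG": 1.0, "CHH": 1.0},  # no conversion
        )
        genomes = simulate_genomes(config)
        reads = simulate_reads(genomes, config)
        bs_reads, _ = bisulfite_convert(reads, genomes, config)
        index = truth_index(genomes)
        cat_config = CategorizerConfig()
        for plain, converted in zip(reads, bs_reads):
            assert converted.seq == plain.seq
            std = categorize_read_via_standard(plain, index, cat_config)
            bs = evaluate_bs_read(
                converted.to_aligned_read(), index, genomes.reference, cat_config
            ).category
            assert bs is std


def categorize_read_via_standard(read, index, config):
    from homeocat.categorizer import categorize

    return categorize(genotype_read(read.to_aligned_read(), index, config), config).category


class TestMethylationReport:
    def test_single_plus_read_cg_site(self, tmp_path, toy_index):
        ref = {"chr1": "ACGTTCAA"}
        sam = tmp_path / "r.sam"
        # read with one conversion at pos 5 (C->T) fixes strand plus;
        # base C at CG-context position 1 is unconverted
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:8\n"
            "r1\t0\tchr1\t1\t60\t8M\t*\t0\t0\tACGTTTAA\tIIIIIIII\n"
        )
        report = methylation_report(sam, ref, toy_index)
        by_pos = {(s.position.pos, s.strand): s for s in report}
        site = by_pos[(1, Strand.plus)]
        assert site.context == "CG"
        assert site.unconverted == 1.0
        assert site.converted == 0.0
        # the read has no index overlap -> category N
        assert site.per_category[Category.N] == [1.0, 0.0]
        converted_site = by_pos[(5, Strand.plus)]
        assert converted_site.converted == 1.0

    def test_ambiguous_read_half_weight(self, tmp_path, toy_index):
        ref = {"chr1": "ACAAAAAA"}
        sam = tmp_path / "r.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:8\n"
            "r1\t0\tchr1\t1\t60\t8M\t*\t0\t0\tACAAAAAA\tIIIIIIII\n"
        )
        report = methylation_report(sam, ref, toy_index)
        assert len(report) == 1
        site = report[0]
        assert site.strand is Strand.plus
        assert site.unconverted == 0.5

    def test_report_conservation(self, tmp_path):
        config = SimConfig(genome_length=3000, depth=8.0, seed=9, snp_density=5.0)
        genomes = simulate_genomes(config)
        reads = simulate_reads(genomes, config)
        bs_reads, _ = bisulfite_convert(reads, genomes, config)
        index = truth_index(genomes)
        sam = tmp_path / "bs.sam"
        write_sam(bs_reads, genomes.lengths, sam)
        report = methylation_report(sam, genomes.reference, index)
        assert report
        for site in report:
            per_cat_u = sum(v[0] for v in site.per_category.values())
            per_cat_c = sum(v[1] for v in site.per_category.values())
            assert per_cat_u == pytest.approx(site.unconverted)
            assert per_cat_c == pytest.approx(site.converted)
            # half-read weights: counts are multiples of 0.5
            assert (site.unconverted * 2) == int(site.unconverted * 2)

    def test_methylation_recovery_within_3se(self, tmp_path):
        levels = {"CG": 0.8, "CHG": 0.5, "CHH": 0.05}
        config = SimConfig(
            genome_length=2000,
            depth=500.0,
            read_length=100,
            seed=17,
            snp_density=2.0,
            conversion_rate=1.0,
            methylation=levels,
        )
        genomes = simulate_genomes(config)
        reads = simulate_reads(genomes, config)
        bs_reads, _ = bisulfite_convert(reads, genomes, config)
        index = truth_index(genomes)
        sam = tmp_path / "bs.sam"
        write_sam(bs_reads, genomes.lengths, sam)
        report = methylation_report(sam, genomes.reference, index)
        totals = {ctx: [0.0, 0.0] for ctx in levels}
        for site in report:
            # exclude sites within 2 bp of an indexed SNP: their context
            # (and identity) differs between the A genome and the reference
            near_snp = index.positions_in(
                site.position.chrom, site.position.pos - 2, site.position.pos + 3
            )
            if site.context in totals and not near_snp:
                totals[site.context][0] += site.unconverted
                totals[site.context][1] += site.converted
        for ctx, p in levels.items():
            unconverted, converted = totals[ctx]
            n = unconverted + converted
            assert n > 1000, ctx
            se = math.sqrt(p * (1 - p) / n)
            assert abs(unconverted / n - p) <= 3 * se, ctx

    def test_write_report(self, tmp_path, toy_index):
        site = MethylSiteReport(
            position=__import__("homeocat.formats_io", fromlist=["GenomicPosition"]).GenomicPosition("chr1", 1),
            strand=Strand.plus,
            context="CG",
        )
        site.per_category[Category.A][0] = 1.5
        out = tmp_path / "report.tsv"
        write_methylation_report([site], out, params={"threshold": 0.75})
        lines = out.read_text().splitlines()
        assert lines[0].startswith("#")
        assert lines[1].split("\t")[:6] == [
            "chrom", "pos", "strand", "context", "total_unconverted", "total_converted",
        ]
        assert lines[2].split("\t")[:6] == ["chr1", "2", "+", "CG", "1.5", "0.0"]
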