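# homeocat

Subgenome categorization of aligned sequencing reads from allopolyploid
organisms.

Allopolyploids carry two coresident parental genomes (here labelled A and
D). `homeocat` builds an index of homoeo-SNPs — fixed single-nucleotide
differences between the two subgenomes, called from alignments of two
diploid-relative read sets to one reference — and then uses that index to
assign each aligned polyploid read to its genome of origin: **A**, **D**,
**X** (chimeric: informative matches to both genomes), or **N** (unknown:
no informative match). Bisulfite-treated libraries are handled with
strand inference from C→T / G→A conversion counts, conversion-tolerant
allele matching, strand-conditional SNP informativeness, and a per-genome
CG/CHG/CHH methylation report.

## What is in the box

| module | purpose |
| --- | --- |
| `homeocat.formats_io` | FASTA reader, samtools-mpileup text parser, CIGAR/coordinate plumbing, SAM via pysam |
| `homeocat.snp_index` | site calling from two per-genome pileups, SNP-type classification, index summary, merge, (de)serialization, SNP-tolerant-mapper and VCF export |
| `homeocat.categorizer` | per-read genotyping at indexed sites, threshold rule (default ≥ 75 % of informative matches), alignment partitioning into `.A/.D/.X/.N` outputs |
| `homeocat.bisulfite` | strand inference, strand-aware matching, CG/CHG/CHH context calls, per-genome methylation report with half-read weighting of ambiguous strands |
| `homeocat.genome_stats` | SNP density per chromosome/window/gene, per-gene SNP histograms, theoretical categorizability fraction for a read length |
| `homeocat.simulator` | seeded generator of diverged genome pairs, labelled pre-aligned reads, bisulfite conversion, and pileups — with truth tables |
| `homeocat.cli` | `homeocat` command with all subcommands and JSON run manifests |

All internal coordinates are 0-based half-open; all serialized text
formats are 1-based (samtools/VCF convention).

## Command-line usage

Generate a synthetic dataset, build an index from the per-genome pileups,
and categorize the reads:

```sh
homeocat simulate --seed 1 --out sim --genome-length 20000 --depth 16
homeocat build-index --pileup-a sim/diploid.A.pileup --pileup-d sim/diploid.D.pileup \
    --out index.tsv --min-coverage 4 --maf 0.40
homeocat categorize --index index.tsv --bam sim/reads.sam --out-prefix out \
    --threshold 0.75 --min-baseq 20 --pair-mode joint
```

This writes `out.A.sam`, `out.D.sam`, `out.X.sam`, `out.N.sam` (each
record tagged `YC` with its category and `YA`/`YD` with its match
tallies), plus `out.stats.tsv`. Use `--tag-only` for a single tagged
output instead.

Bisulfite data and methylation calling:

```sh
homeocat categorize-bs --index index.tsv --bam bs_reads.sam \
    --reference reference.fasta --out-prefix bs
homeocat methcall --bam bs.tagged.sam --reference reference.fasta \
    --index index.tsv --out methylation.tsv
```

Index statistics and export for SNP-tolerant mapping:

```sh
homeocat index-stats --index index.tsv --reference reference.fasta \
    --gff3 genes.gff3 --read-length 100 --out-prefix stats
homeocat export-gsnap --index index.tsv --out snps.txt
```

Exit codes: 0 success, 1 usage error, 2 data error. A `key = value`
config file can supply defaults via `homeocat --config FILE <subcommand>`
(explicit flags win). Every run writes a `*.manifest.json` with
parameters, input checksums, and the tool version.

## Index file format

Tab-delimited with `#key=value` header lines:

```
#reference=ref
#min_coverage=4
chrom  pos(1-based)  ref  alleles_A  alleles_D  snp_type
```

`snp_type` is `transition`, `transversion`, or `multi_allele`
(multi-allele: more than one base qualified in a genome). Allele sets of
the two genomes are always disjoint; the reader enforces this.

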