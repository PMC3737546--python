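# bacrnaseq

Analysis of bacterial RNA-seq experiments, from raw reads to a genome-wide
picture of transcription: where transcripts start and end, how strongly each
gene is expressed, which genes change between conditions, and which adjacent
genes are transcribed together as operons.

Bacterial genome annotations give translation boundaries for protein-coding
genes but rarely transcription boundaries, and they miss many small
regulatory RNAs. `bacrnaseq` takes a reference genome (FASTA), NCBI-style
annotations (PTT/RNT) and single-end sequencing reads (FASTQ, QSEQ or FASTA)
and produces a transcriptome map with 5′/3′ UTRs and novel sRNA calls,
upper-quartile-normalized expression values, negative-binomial exact tests
for differential expression, and naive-Bayes operon predictions. A
synthetic-data generator with complete ground truth makes every stage
verifiable on a laptop.

## Methods at a glance

- **Alignment.** An FM-index over the Burrows–Wheeler transform of the
  genome gives O(m) exact matching for a read of length m. Reads without a
  perfect match are partitioned into non-overlapping seeds (pigeonhole: an
  alignment with ≤ k edits leaves a seed exact), and candidate loci are
  scored with a banded dynamic program whose mismatch penalty is the base's
  Phred score capped at 30 and whose indel penalty is 30, subject to
  k = ⌈0.15·m⌉ edits. Co-optimal placements are all reported with weight
  1/n_optimal.
- **Transcript boundaries.** Transcript seeds are annotated genes plus
  maximal runs of ≥ w = 10 nt with coverage ≥ T (T = max(2, ⌈mean
  coverage⌉)). Each seed is extended by a Bayesian two-class rule: a flanking
  window joins the transcript if its read count x_r is at least as likely
  under Poisson(λ) fitted to the seed as under a geometric background fitted
  to antisense coverage over coding genes. Overlapping or similar abutting
  seeds are merged; unannotated transcripts are classified intergenic or
  antisense.
- **Quantification.** Counts are normalized per sample by the upper
  quartile of non-zero gene counts (robust to a few dominant transcripts);
  expression = K·count / ((length/1000)·UQ).
- **Differential expression.** R1, R2 are per-condition sums of normalized
  counts. Per-gene variances (true replicates, or the two conditions as
  surrogate replicates) are smoothed against the mean by lowess; the
  two-sided P-value sums, over all splits of S = R1+R2, the probabilities
  p(x, S−x) ≤ p(R1, R2) under independent negative binomials;
  Benjamini–Hochberg q-values control FDR at 1%.
- **Operons.** The prior that an adjacent same-strand pair is co-transcribed
  is 1 − (directons / same-strand adjacent pairs). Two Epanechnikov-KDE
  likelihoods — intergenic distance (same-strand vs opposite-strand
  training distances) and Pearson correlation of log expression across
  samples — combine in a naive Bayes posterior; pairs above 0.5 chain into
  operons.

## Worked example

Simulate a two-condition experiment (50 kb genome, 30 genes in operons,
2 replicates each, ~20× coverage) and analyse it:

```bash
bacrnaseq simulate --out demo --genome-length 50000 --genes 30 --depth 20 --seed 11
bacrnaseq run --genome demo/genome.fna --ptt demo/genome.ptt \
    --reads demo/cond1_rep1.fastq,demo/cond1_rep2.fastq \
    --reads demo/cond2_rep1.fastq,demo/cond2_rep2.fastq \
    --out demo_out --seed 11
```

`demo_out/transcripts.tsv` starts:

```
transcript_id  start  stop  strand  kind  genes              utr5  utr3
T00001         177    2076  +       mRNA  g0001,g0002,g0003  21    40
T00002         2150   3034  -       mRNA  g0004              3     2
```

The first transcript covers a three-gene operon transcribed from a start
site 21 nt upstream of g0001's start codon (its 5′ UTR) and ending 40 nt
past the last stop codon. `demo_out/diffexp.tsv` ranks genes by q-value:

```
gene               R1      R2       fold_change  pvalue       qvalue       significant
g0001+g0002+g0003  1765.8  7137.43  4.04031      7.85499e-53  1.02115e-51  yes
```

— the planted 4-fold induction of that operon is recovered (R1, R2 are
normalized read sums per condition). `demo_out/operons.tsv` lists the
predicted multi-gene operons with their weakest link posterior:

```
operon_id  strand  genes              start  stop  min_posterior
OP0001     +       g0001,g0002,g0003  198    2036  0.6376
```

All four samples align completely (`manifest.json` reports per-sample
alignment fractions; the simulated reads carry Phred-consistent errors,
which the quality-aware alignment absorbs). Coverage WIG tracks and a GFF3
of novel transcripts are written alongside for genome-browser inspection.

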