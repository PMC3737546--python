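"""Synthetic bacterial RNA-seq experiments with full ground truth.

The generator emulates the study conditions of a simulated prokaryotic
RNA-seq experiment: a random genome, an operon/directon gene layout,
expression levels drawn from a mixed power-law/exponential distribution,
transcription-start-site jitter with exponential(mean 25 nt) tails,
uniform random fragmentation (uniform read starts within transcripts) and
Phred-consistent base errors, so that every pipeline stage can be scored
against known truth without external data.

Defaults (units in nt unless noted): within-operon gaps mean 20 (may
overlap), between-directon gaps mean 150, mean operon size 3 genes, TSS
jitter mean 25, read length 72, base quality 30.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .formats_io import GeneAnnotation, GenomeRecord, ReadRecord, to_internal

logger = logging.getLogger("bacrnaseq")

_BASES = np.array(list("ACGT"))


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_genome(length: int, gc: float = 0.5, seed=0) -> GenomeRecord:
    """IID random genome with the requested GC fraction."""
    if length < 1000:
        raise ValueError("genome length must be at least 1000 nt")
    if not 0 < gc <= 1:
        raise ValueError("gc must be in (0, 1]")
    rng = _rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(rng.choice(_BASES, size=length, p=p))
    return GenomeRecord(id="simchr", seq=seq)


@dataclass
class OperonGeometry:
    """Gene/operon layout parameters for :func:`simulate_annotation`."""

    # geometric operon sizes with mean 2.5 genes give a co-transcription
    # base rate around 0.75 among same-strand pairs, matching the prior
    # range observed in real enterobacterial annotations
    mean_operon_size: float = 2.5
    within_gap_mean: float = 20.0  # gamma-shaped, shifted so some genes overlap
    # gaps between transcription units: a 60 nt floor (room for a
    # terminator and a promoter) plus an exponential tail, mean 150 total
    between_gap_mean: float = 90.0
    between_gap_min: int = 60
    gene_len_mean: float = 800.0
    gene_len_min: int = 100
    p_same_strand: float = 0.5  # next directon keeps the strand with this prob


def simulate_annotation(genome: GenomeRecord, n_genes: int,
                        geometry: OperonGeometry | None = None, seed=0
                        ) -> tuple[list[GeneAnnotation], pd.DataFrame]:
    """Place genes in operons along the genome.

    Returns the annotations plus a truth table with one row per gene:
    locus id, operon id, and whether the pair (gene, next gene) is
    co-transcribed.
    """
    geom = geometry or OperonGeometry()
    rng = _rng(seed)
    genes: list[GeneAnnotation] = []
    rows = []
    pos = int(rng.integers(50, 200))
    operon_id = 0
    strand = "+" if rng.random() < 0.5 else "-"
    while len(genes) < n_genes:
        operon_id += 1
        size = rng.geometric(1.0 / geom.mean_operon_size)
        size = int(min(size, n_genes - len(genes)))
        for j in range(size):
            glen = max(geom.gene_len_min, int(rng.gamma(4.0, geom.gene_len_mean / 4.0)))
            stop = pos + glen - 1
            if stop + 1 >= genome.n - 200:
                break
            locus = f"g{len(genes) + 1:04d}"
            genes.append(GeneAnnotation(start=pos + 1, stop=stop + 1, strand=strand,
                                        locus_id=locus, kind="CDS",
                                        product="hypothetical protein"))
            rows.append({"locus_id": locus, "operon": operon_id,
                         "cotranscribed_with_next": j < size - 1})
            if j < size - 1:
                # translationally coupled genes overlap in ~a quarter of
                # within-operon pairs; the rest sit a short gamma-shaped
                # gap apart (overall mean == within_gap_mean)
                if rng.random() < 0.25:
                    gap = -int(rng.integers(1, 16))
                else:
                    m = (geom.within_gap_mean + 0.25 * 8.0) / 0.75
                    gap = int(round(rng.gamma(3.0, m / 3.0)))
                # co-transcribed genes sit closer than the terminator +
                # promoter footprint that separates independent units
                gap = min(gap, geom.between_gap_min - 5)
                gap = max(gap, -glen // 2)
            else:
                gap = geom.between_gap_min + int(round(
                    rng.exponential(geom.between_gap_mean)))
            pos = stop + 1 + gap
        else:
            if rng.random() >= geom.p_same_strand:
                strand = "+" if strand == "-" else "-"
            continue
        break
    if len(genes) < 2:
        raise ValueError("genome too short for the requested gene layout")
    if len(genes) < n_genes:
        logger.warning("genome exhausted after %d of %d genes", len(genes), n_genes)
    truth = pd.DataFrame(rows).set_index("locus_id")
    # the last gene of the run never has a co-transcribed successor
    truth.iloc[-1, truth.columns.get_loc("cotranscribed_with_next")] = False
    return genes, truth


def simulate_expression(annotations: Sequence[GeneAnnotation],
                        operon_truth: pd.DataFrame, conditions: int = 2,
                        de_fraction: float = 0.0, fold: float = 4.0,
                        condition_sd: float = 0.0, theta: float = 200.0,
                        seed=0) -> tuple[pd.DataFrame, pd.Series]:
    """Ground-truth relative abundances per gene and condition.

    Baseline abundance is drawn per operon from a mixed law: with
    probability 1/2 exponential (mean ``theta``), otherwise Pareto with
    tail index 1.5 (truncated at 100x theta), giving the heavy upper tail
    characteristic of bacterial expression.  Genes of an operon share one
    abundance.  ``condition_sd`` adds per-operon log-normal variation
    across conditions (for correlation-based analyses); a ``de_fraction``
    of genes is multiplied by ``fold`` in the second condition.
    Returns (expression DataFrame, per-gene true fold-change Series).
    """
    if conditions < 1:
        raise ValueError("need at least one condition")
    rng = _rng(seed)
    operons = operon_truth["operon"].to_numpy()
    uniq = np.unique(operons)
    base_by_op = {}
    for op in uniq:
        if rng.random() < 0.5:
            v = rng.exponential(theta)
        else:
            v = theta * 0.2 * (rng.pareto(1.5) + 1)
            v = min(v, 100 * theta)
        base_by_op[op] = max(v, 1e-3)
    n = len(annotations)
    # condition-level variation is shared within an operon so that member
    # genes stay perfectly correlated across conditions
    factors = {op: (rng.lognormal(0.0, condition_sd, size=conditions)
                    if condition_sd > 0 else np.ones(conditions))
               for op in uniq}
    expr = np.empty((n, conditions))
    for i, g in enumerate(annotations):
        op = operon_truth.loc[g.locus_id, "operon"]
        expr[i, :] = base_by_op[op] * factors[op]
    # differential expression is planted per operon so that member genes
    # keep sharing one abundance in every condition
    fold_truth = pd.Series(1.0, index=[g.locus_id for g in annotations])
    if de_fraction > 0 and conditions >= 2:
        k = max(1, int(round(de_fraction * len(uniq))))
        de_ops = set(rng.choice(uniq, size=k, replace=False).tolist())
        for i, g in enumerate(annotations):
            if operon_truth.loc[g.locus_id, "operon"] in de_ops:
                expr[i, 1] *= fold
                fold_truth.iloc[i] = fold
    df = pd.DataFrame(expr, index=[g.locus_id for g in annotations],
                      columns=[f"cond{c + 1}" for c in range(conditions)])
    return df, fold_truth


@dataclass
class TranscriptTruth:
    """True transcript extents (0-based half-open) after TSS jitter."""

    operon: int
    start: int
    end: int
    strand: str
    genes: tuple[str, ...]
    tss: int  # genomic offset of the first transcribed nucleotide
    utr5: int


def simulate_transcripts(annotations: Sequence[GeneAnnotation],
                         operon_truth: pd.DataFrame,
                         tss_jitter_mean: float = 25.0,
                         utr3_mean: float = 15.0, genome_len: int | None = None,
                         seed=0) -> list[TranscriptTruth]:
    """One transcript per operon; the 5' end extends upstream of the first
    gene by an exponential(mean ``tss_jitter_mean``) UTR, the 3' end by an
    exponential(mean ``utr3_mean``) tail (both truncated at the genome)."""
    rng = _rng(seed)
    out = []
    by_op: dict[int, list[GeneAnnotation]] = {}
    for g in annotations:
        by_op.setdefault(int(operon_truth.loc[g.locus_id, "operon"]), []).append(g)
    for op, genes in sorted(by_op.items()):
        s = min(to_internal(g.start, g.stop)[0] for g in genes)
        e = max(to_internal(g.start, g.stop)[1] for g in genes)
        strand = genes[0].strand
        utr5 = int(round(rng.exponential(tss_jitter_mean)))
        utr3 = int(round(rng.exponential(utr3_mean)))
        if strand == "+":
            start = max(0, s - utr5)
            end = e + utr3 if genome_len is None else min(genome_len, e + utr3)
            tss = start
        else:
            start = max(0, s - utr3)
            end = e + utr5 if genome_len is None else min(genome_len, e + utr5)
            tss = end - 1
        out.append(TranscriptTruth(operon=op, start=start, end=end, strand=strand,
                                   genes=tuple(g.locus_id for g in genes),
                                   tss=tss, utr5=utr5))
    return out


def simulate_reads(genome: GenomeRecord, transcripts: Sequence[TranscriptTruth],
                   abundances: pd.Series, depth: float = 20.0,
                   read_len: int = 72, base_quality: int = 30,
                   error_model: bool = True, seed=0, id_prefix: str = "r",
                   ) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Sample strand-specific reads from the true transcripts.

    Read counts per transcript are Poisson with mean proportional to
    abundance x length, globally scaled so realized mean coverage over
    expressed transcripts is ``depth``.  Start positions are uniform
    within the transcript (uniform fragmentation); each base is flipped
    to a random other base with probability 10^(-q/10) when the error
    model is on.  Returns the reads plus a truth table of origins.

    ``abundances`` is indexed by the locus id of a transcript's first gene
    (operon members share it).
    """
    if read_len < 20:
        raise ValueError("read length must be at least 20")
    rng = _rng(seed)
    usable = [t for t in transcripts if t.end - t.start >= read_len]
    weights = np.array([float(abundances[t.genes[0]]) * (t.end - t.start)
                        for t in usable])
    if weights.sum() <= 0:
        return [], pd.DataFrame(columns=["read_id", "pos", "strand", "operon"])
    total_span = sum(t.end - t.start for t in usable)
    n_reads_target = depth * total_span / read_len
    lam = weights / weights.sum() * n_reads_target
    reads: list[ReadRecord] = []
    origin_rows = []
    comp = str.maketrans("ACGTN", "TGCAN")
    gseq = genome.seq
    for t, l in zip(usable, lam):
        count = int(rng.poisson(l))
        if count == 0:
            continue
        starts = rng.integers(t.start, t.end - read_len + 1, size=count)
        for s in np.sort(starts):
            s = int(s)
            frag = gseq[s:s + read_len]
            if t.strand == "-":
                frag = frag.translate(comp)[::-1]
            quals = np.full(read_len, base_quality, dtype=np.int16)
            if error_model:
                perr = 10.0 ** (-quals / 10.0)
                flip = rng.random(read_len) < perr
                if flip.any():
                    chars = list(frag)
                    for i in np.flatnonzero(flip):
                        alternatives = [b for b in "ACGT" if b != chars[i]]
                        chars[i] = alternatives[int(rng.integers(3))]
                    frag = "".join(chars)
            rid = f"{id_prefix}{len(reads) + 1:07d}"
            reads.append(ReadRecord(id=rid, seq=frag, quals=quals))
            origin_rows.append({"read_id": rid, "pos": s, "strand": t.strand,
                                "operon": t.operon})
    origins = pd.DataFrame(origin_rows)
    return reads, origins


def simulate_model_coverage(n: int, transcripts: Sequence[TranscriptTruth],
                            depth_by_operon: dict[int, float],
                            bg_mean: float = 0.1, seed=0):
    """Per-nucleotide coverage drawn from the boundary model's own
    assumptions: Poisson(depth) inside each transcript on its strand,
    geometric(mean ``bg_mean``) background everywhere.

    Returns a :class:`~bacrnaseq.transcriptome.StrandCoverage`.
    """
    from .transcriptome import StrandCoverage

    rng = _rng(seed)
    cov = StrandCoverage(n, stranded=True)
    p = 1.0 / (1.0 + bg_mean)
    for strand in "+-":
        arr = cov.get(strand)
        arr += rng.geometric(p, size=n) - 1  # geometric on {0,1,2,...}
    for t in transcripts:
        d = depth_by_operon.get(t.operon, 0.0)
        if d <= 0:
            continue
        cov.get(t.strand)[t.start:t.end] += rng.poisson(d, size=t.end - t.start)
    return cov


# ---------------------------------------------------------------------------
# on-disk dataset


def write_ptt(annotations: Sequence[GeneAnnotation], genome: GenomeRecord,
              path, kind: str = "CDS") -> None:
    rows = [g for g in annotations if g.kind == kind]
    with open(path, "w") as fh:
        fh.write(f"{genome.id} - 1..{genome.n}\n")
        fh.write(f"{len(rows)} proteins\n")
        fh.write("Location\tStrand\tLength\tPID\tGene\tSynonym\tCode\tCOG\tProduct\n")
        for g in rows:
            fh.write(f"{g.start}..{g.stop}\t{g.strand}\t{(g.length - 3) // 3}\t-\t-\t"
                     f"{g.locus_id}\t-\t-\t{g.product}\n")


def write_fastq(reads: Sequence[ReadRecord], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(int(q) + 33) for q in r.quals)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")


def write_fasta(genome: GenomeRecord, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.id}\n")
        for i in range(0, genome.n, width):
            fh.write(genome.seq[i:i + width] + "\n")


def simulate_dataset(out_dir, genome_length: int = 100_000, n_genes: int = 60,
                     conditions: int = 2, replicates: int = 2,
                     depth: float = 20.0, read_len: int = 72,
                     de_fraction: float = 0.1, fold: float = 4.0,
                     gc: float = 0.5, seed: int = 0) -> dict:
    """Write a complete synthetic experiment (genome, PTT, FASTQ, truth TSVs)
    and return the in-memory objects."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    genome = simulate_genome(genome_length, gc=gc, seed=rng)
    annotations, operon_truth = simulate_annotation(genome, n_genes, seed=rng)
    expr, fold_truth = simulate_expression(annotations, operon_truth,
                                           conditions=conditions,
                                           de_fraction=de_fraction, fold=fold,
                                           seed=rng)
    transcripts = simulate_transcripts(annotations, operon_truth,
                                       genome_len=genome.n, seed=rng)
    write_fasta(genome, out / "genome.fna")
    write_ptt(annotations, genome, out / "genome.ptt")
    sample_files = {}
    for c in range(conditions):
        for r in range(replicates):
            sample = f"cond{c + 1}_rep{r + 1}"
            reads, origins = simulate_reads(
                genome, transcripts, expr.iloc[:, c],
                depth=depth, read_len=read_len, seed=rng,
                id_prefix=f"{sample}_")
            write_fastq(reads, out / f"{sample}.fastq")
            origins.to_csv(out / f"{sample}.origins.tsv", sep="\t", index=False)
            sample_files[sample] = out / f"{sample}.fastq"
    expr.to_csv(out / "truth_expression.tsv", sep="\t")
    fold_truth.rename("fold").to_csv(out / "truth_de.tsv", sep="\t")
    operon_truth.to_csv(out / "truth_operons.tsv", sep="\t")
    pd.DataFrame([{"operon": t.operon, "start": t.start, "end": t.end,
                   "strand": t.strand, "tss": t.tss, "utr5": t.utr5}
                  for t in transcripts]).to_csv(out / "truth_transcripts.tsv",
                                                sep="\t", index=False)
    return {"genome": genome, "annotations": annotations,
            "operon_truth": operon_truth, "expression": expr,
            "fold_truth": fold_truth, "transcripts": transcripts,
            "sample_files": sample_files}
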