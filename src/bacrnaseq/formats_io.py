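"""Readers and writers for the external formats the pipeline touches.

Genomes arrive as FASTA, gene annotations as NCBI PTT (protein-coding) and
RNT (RNA genes), and sequencing reads as FASTQ (Sanger quality encoding),
QSEQ or FASTA.  Results are written as tab-delimited reports, fixed-step WIG
coverage tracks and GFF3 features.

Coordinate conventions: everything external (PTT/RNT, GFF3, WIG, reports)
is 1-based inclusive, matching the annotation dialect; everything internal
is 0-based half-open.  :func:`to_internal` and :func:`to_external` are the
two converters and are exact inverses.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger("bacrnaseq")

_IUPAC_TO_N = str.maketrans(
    {c: "N" for c in "RYSWKMBDHVryswkmbdhv"}
)

#: default Phred quality assigned to FASTA reads (no quality information)
DEFAULT_FASTA_QUALITY = 30

#: QSEQ files carry Illumina-style qualities (ASCII offset 64)
QSEQ_QUALITY_OFFSET = 64


class FormatError(ValueError):
    """Malformed or empty input file."""


class EmptyFasta(FormatError):
    """FASTA file contained no sequence."""


class NoExpressedGenes(ValueError):
    """All genes have zero counts; upper-quartile normalization undefined."""


@dataclass
class GenomeRecord:
    """A reference replicon: identifier plus upper-case sequence over ACGTN."""

    id: str
    seq: str

    @property
    def n(self) -> int:
        return len(self.seq)

    def __post_init__(self) -> None:
        if not self.seq:
            raise EmptyFasta("genome sequence is empty")
        bad = set(self.seq) - set("ACGTN")
        if bad:
            raise FormatError(f"genome contains unexpected symbols: {sorted(bad)}")


@dataclass
class GeneAnnotation:
    """An annotated gene in 1-based inclusive genomic coordinates."""

    start: int
    stop: int
    strand: str
    locus_id: str
    kind: str = "CDS"  # CDS or RNA
    product: str = ""

    def __post_init__(self) -> None:
        if self.start > self.stop:
            self.start, self.stop = self.stop, self.start
        if self.strand not in "+-":
            raise FormatError(f"bad strand {self.strand!r} for {self.locus_id}")

    @property
    def length(self) -> int:
        return self.stop - self.start + 1


@dataclass
class ReadRecord:
    """A sequencing read with per-base Phred qualities (Sanger scale)."""

    id: str
    seq: str
    quals: np.ndarray

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int16)
        if len(self.quals) != len(self.seq):
            raise FormatError(f"read {self.id}: quality/sequence length mismatch")


@dataclass
class RunConfig:
    """Tunable parameters of a pipeline run.

    ``k_frac`` is the banded-alignment edit budget as a fraction of read
    length; ``seed_min_len`` (w) the minimum novel transcript seed length;
    ``extension_step`` the window size used when extending transcript seeds;
    ``merge_ratio`` the maximum mean-coverage ratio for merging abutting
    seeds; ``scale_k`` the constant of the upper-quartile expression measure;
    ``fdr`` the q-value cutoff for differential expression; and
    ``operon_cutoff`` the posterior threshold for chaining gene pairs into
    operons.
    """

    k_frac: float = 0.15
    seed_min_len: int = 10
    extension_step: int = 5
    merge_ratio: float = 2.0
    scale_k: float = 1000.0
    fdr: float = 0.01
    operon_cutoff: float = 0.5
    strandedness: str = "fwd"  # fwd | rev | none
    min_read_len: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0,1)")
        for name in ("k_frac", "seed_min_len", "extension_step", "merge_ratio",
                     "scale_k", "operon_cutoff", "min_read_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.strandedness not in ("fwd", "rev", "none"):
            raise ValueError("strandedness must be fwd, rev or none")


# ---------------------------------------------------------------------------
# coordinate conversion


def to_internal(start: int, stop: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, stop


def to_external(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start + 1, end


# ---------------------------------------------------------------------------
# input readers


def _sanitize_nt(seq: str) -> str:
    seq = seq.upper().replace("U", "T")
    seq = seq.translate(_IUPAC_TO_N)
    return seq


def read_fasta(path: str | os.PathLike) -> GenomeRecord:
    """Read the first record of a FASTA file as the reference genome.

    Lower-case and RNA bases are normalized, IUPAC ambiguity codes become N.
    Multi-record files use the first record with a warning (single-replicon
    genomes only).
    """
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyFasta(f"{path}: no FASTA records")
    if len(records) > 1:
        logger.warning("%s: %d records; using the first (%s)",
                       path, len(records), records[0].id)
    seq = _sanitize_nt(str(records[0].seq))
    if not seq:
        raise EmptyFasta(f"{path}: empty sequence")
    return GenomeRecord(id=records[0].id, seq=seq)


def _parse_ptt_like(path: str | os.PathLike, kind: str) -> list[GeneAnnotation]:
    out: list[GeneAnnotation] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    # NCBI dialect: description line, gene-count line, column-header line
    for i, line in enumerate(lines[3:], start=4):
        if not line.strip():
            continue
        cols = line.split("\t")
        loc = cols[0].strip()
        if ".." not in loc:
            logger.warning("%s line %d: malformed location %r; skipped", path, i, loc)
            continue
        try:
            a, b = loc.split("..")
            start, stop = int(a), int(b)
        except ValueError:
            logger.warning("%s line %d: malformed location %r; skipped", path, i, loc)
            continue
        strand = cols[1].strip() if len(cols) > 1 else "+"
        if strand in ("−",):  # unicode minus
            strand = "-"
        if strand not in "+-":
            logger.warning("%s line %d: bad strand %r; skipped", path, i, strand)
            continue
        synonym = cols[5].strip() if len(cols) > 5 else f"{kind}_{i}"
        product = cols[8].strip() if len(cols) > 8 else ""
        if start > stop:
            logger.warning("%s line %d: reversed location %d..%d normalized",
                           path, i, start, stop)
        out.append(GeneAnnotation(start=start, stop=stop, strand=strand,
                                  locus_id=synonym, kind=kind, product=product))
    return out


def read_annotations(ptt_path: str | os.PathLike | None,
                     rnt_path: str | os.PathLike | None = None,
                     ) -> list[GeneAnnotation]:
    """Parse NCBI PTT (CDS) and RNT (RNA gene) tables, sorted by start."""
    genes: list[GeneAnnotation] = []
    if ptt_path is not None and Path(ptt_path).exists():
        genes += _parse_ptt_like(ptt_path, "CDS")
    elif ptt_path is not None:
        logger.warning("PTT file %s missing; proceeding without CDS annotations", ptt_path)
    if rnt_path is not None and Path(rnt_path).exists():
        genes += _parse_ptt_like(rnt_path, "RNA")
    elif rnt_path is not None:
        logger.warning("RNT file %s missing; proceeding without RNA annotations", rnt_path)
    genes.sort(key=lambda g: (g.start, g.stop))
    return genes


def _read_fastq(path) -> Iterator[ReadRecord]:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) % 4 not in (0,):
        # allow trailing blank lines
        while lines and not lines[-1].strip():
            lines.pop()
    for idx in range(0, len(lines), 4):
        chunk = lines[idx:idx + 4]
        if len(chunk) < 4:
            raise FormatError(f"{path}: truncated FASTQ record #{idx // 4 + 1}")
        hdr, seq, plus, qual = chunk
        if not hdr.startswith("@") or not plus.startswith("+"):
            raise FormatError(f"{path}: malformed FASTQ record #{idx // 4 + 1}")
        if len(seq) != len(qual):
            raise FormatError(f"{path}: length mismatch in record #{idx // 4 + 1}")
        quals = np.frombuffer(qual.encode(), dtype=np.uint8).astype(np.int16) - 33
        yield ReadRecord(id=hdr[1:].split()[0], seq=_sanitize_nt(seq), quals=quals)


def _read_fasta_reads(path) -> Iterator[ReadRecord]:
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _sanitize_nt(str(rec.seq))
        yield ReadRecord(id=rec.id, seq=seq,
                         quals=np.full(len(seq), DEFAULT_FASTA_QUALITY, dtype=np.int16))


def _read_qseq(path) -> Iterator[ReadRecord]:
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 11:
                raise FormatError(f"{path} line {i}: expected 11 QSEQ columns")
            if cols[10].strip() == "0":  # failed chastity filter
                continue
            seq = cols[8].replace(".", "N")
            quals = (np.frombuffer(cols[9].encode(), dtype=np.uint8).astype(np.int16)
                     - QSEQ_QUALITY_OFFSET)
            quals[np.frombuffer(cols[8].encode(), dtype=np.uint8) == ord(".")] = 0
            rid = ":".join(cols[0:6])
            yield ReadRecord(id=rid, seq=_sanitize_nt(seq), quals=quals)


def read_reads(path: str | os.PathLike, format: str | None = None,
               ) -> Iterator[ReadRecord]:
    """Stream sequencing reads from FASTQ, QSEQ or FASTA.

    FASTA reads get a uniform Phred quality of 30; QSEQ '.' bases become N
    with quality 0 and non-pass-filter reads are dropped.
    """
    if format is None:
        suffix = Path(path).suffix.lower()
        format = {".fastq": "fastq", ".fq": "fastq", ".qseq": "qseq",
                  ".txt": "qseq", ".fasta": "fasta", ".fa": "fasta",
                  ".fna": "fasta"}.get(suffix, "fastq")
    if format == "fastq":
        return _read_fastq(path)
    if format == "fasta":
        return _read_fasta_reads(path)
    if format == "qseq":
        return _read_qseq(path)
    raise ValueError(f"unknown read format {format!r}")


# ---------------------------------------------------------------------------
# output writers


def write_transcripts_tsv(transcripts, path) -> None:
    cols = ["transcript_id", "start", "stop", "strand", "kind",
            "genes", "utr5", "utr3"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for i, t in enumerate(transcripts):
            s, e = to_external(t.start, t.end)
            fh.write("\t".join([
                f"T{i + 1:05d}", str(s), str(e), t.strand, t.kind,
                ",".join(t.genes), str(t.utr5), str(t.utr3),
            ]) + "\n")


def read_transcripts_tsv(path):
    """Round-trip reader for transcripts.tsv (used for validation)."""
    from .transcriptome import Transcript

    out = []
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("transcript_id")
        for line in fh:
            tid, s, e, strand, kind, genes, u5, u3 = line.rstrip("\n").split("\t")
            start, end = to_internal(int(s), int(e))
            out.append(Transcript(start=start, end=end, strand=strand, kind=kind,
                                  genes=tuple(g for g in genes.split(",") if g),
                                  utr5=int(u5), utr3=int(u3)))
    return out


def write_expression_tsv(expr_df, lengths, path) -> None:
    df = expr_df.copy()
    df.insert(0, "length", [lengths[i] for i in df.index])
    df.index.name = "transcript_id"
    df.to_csv(path, sep="\t", float_format="%.6g")


def write_diffexp_tsv(records, path, fdr: float = 0.01) -> None:
    cols = ["gene", "R1", "R2", "fold_change", "pvalue", "qvalue", "significant"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            fh.write("\t".join([
                r.gene, f"{r.r1:.6g}", f"{r.r2:.6g}", f"{r.fold_change:.6g}",
                f"{r.pvalue:.6g}", f"{r.qvalue:.6g}",
                "yes" if r.qvalue < fdr else "no",
            ]) + "\n")


def write_operons_tsv(operons, path) -> None:
    cols = ["operon_id", "strand", "genes", "start", "stop", "min_posterior"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for i, op in enumerate(operons):
            s, e = to_external(op.start, op.end)
            fh.write("\t".join([
                f"OP{i + 1:04d}", op.strand, ",".join(op.genes),
                str(s), str(e), f"{op.min_posterior:.4f}",
            ]) + "\n")


def write_wig(coverage, genome_id: str, path, track_name: str = "coverage") -> None:
    """Fixed-step WIG, one value per nucleotide, 1-based."""
    with open(path, "w") as fh:
        fh.write(f'track type=wiggle_0 name="{track_name}"\n')
        fh.write(f"fixedStep chrom={genome_id} start=1 step=1\n")
        np.savetxt(fh, np.asarray(coverage), fmt="%.4g")


def write_novel_gff3(transcripts, genome_id: str, path) -> None:
    """Novel (unannotated) transcripts as GFF3 ncRNA features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        i = 0
        for t in transcripts:
            if not t.kind.startswith("novel"):
                continue
            i += 1
            s, e = to_external(t.start, t.end)
            attrs = f"ID=novel{i:04d};kind={t.kind}"
            fh.write("\t".join([genome_id, "bacrnaseq", "ncRNA", str(s), str(e),
                                ".", t.strand, ".", attrs]) + "\n")


def write_outputs(results: dict, out_dir: str | os.PathLike) -> list[Path]:
    """Write all pipeline reports into ``out_dir``; returns the paths written.

    Expects keys (all optional except genome): ``genome``, ``transcripts``,
    ``expression`` (DataFrame) with ``lengths``, ``diffexp`` (DERecord list),
    ``operons``, ``coverage`` (mapping sample -> StrandCoverage).
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise FormatError(f"output directory {out} is not writable: {exc}")

    written: list[Path] = []
    genome = results["genome"]
    if "transcripts" in results:
        p = out / "transcripts.tsv"
        write_transcripts_tsv(results["transcripts"], p)
        written.append(p)
        p = out / "novel_transcripts.gff3"
        write_novel_gff3(results["transcripts"], genome.id, p)
        written.append(p)
    if "expression" in results:
        p = out / "expression.tsv"
        write_expression_tsv(results["expression"], results["lengths"], p)
        written.append(p)
    if "diffexp" in results:
        p = out / "diffexp.tsv"
        write_diffexp_tsv(results["diffexp"], p, results.get("fdr", 0.01))
        written.append(p)
    if "operons" in results:
        p = out / "operons.tsv"
        write_operons_tsv(results["operons"], p)
        written.append(p)
    for sample, cov in results.get("coverage", {}).items():
        for strand, arr in cov.tracks():
            tag = {"+": "plus", "-": "minus", ".": "both"}[strand]
            p = out / f"coverage_{sample}_{tag}.wig"
            write_wig(arr, genome.id, p, track_name=f"{sample} ({strand})")
            written.append(p)
    return written
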