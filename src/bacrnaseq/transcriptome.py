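"""Transcriptome-map construction from aligned reads.

Transcript seeds are annotated genes plus maximal runs of high coverage
(every nucleotide covered by at least T reads over at least w consecutive
positions).  Each seed is extended outward by a Bayesian two-class decision:
an adjacent window belongs to the transcript if its read count is more
likely under a Poisson distribution fitted to the seed's coverage than
under the genome-wide antisense background, modeled as a geometric
distribution (a sum over a multi-nucleotide window being negative
binomial).  With uniform class priors the maximum a posteriori choice
reduces to comparing the two likelihoods; ties extend.  Extended seeds
that overlap are merged, abutting seeds merge when their mean coverages
are within a factor ``merge_ratio``.  Transcripts that contain annotated
genes report 5' and 3' UTR lengths; the rest are classified as novel
intergenic or novel antisense small RNAs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from math import ceil
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .align import AlignmentRecord
from .formats_io import GeneAnnotation, RunConfig, to_internal

logger = logging.getLogger("bacrnaseq")


class StrandCoverage:
    """Per-nucleotide, per-strand aligned-read depth (fractional weights).

    For unstranded libraries a single pooled track backs both strands.
    """

    def __init__(self, n: int, stranded: bool = True):
        self.n = n
        self.stranded = stranded
        if stranded:
            self._arr = {"+": np.zeros(n), "-": np.zeros(n)}
        else:
            pooled = np.zeros(n)
            self._arr = {"+": pooled, "-": pooled}

    def get(self, strand: str) -> np.ndarray:
        return self._arr[strand]

    def add(self, strand: str, start: int, end: int, weight: float) -> None:
        self._arr[strand][start:end] += weight

    def tracks(self):
        """(strand label, array) pairs for the distinct underlying tracks."""
        if self.stranded:
            yield "+", self._arr["+"]
            yield "-", self._arr["-"]
        else:
            yield ".", self._arr["+"]

    @property
    def total_mass(self) -> float:
        return float(sum(arr.sum() for _, arr in self.tracks()))


@dataclass
class TranscriptSeed:
    """A candidate transcript interval (0-based half-open)."""

    start: int
    end: int
    strand: str
    origin: tuple[str, ...] = ()  # locus ids of annotated genes, or () for novel
    core_start: int = -1  # pre-extension bounds; trimming never enters the core
    core_end: int = -1

    def __post_init__(self) -> None:
        if self.core_start < 0:
            self.core_start = self.start
        if self.core_end < 0:
            self.core_end = self.end


@dataclass
class ExtensionModel:
    """Poisson transcript rate and geometric background for seed extension."""

    lam: float
    p_bg: float

    def __post_init__(self) -> None:
        if not 0 < self.p_bg <= 1:
            raise ValueError("p_bg must be in (0, 1]")


@dataclass
class Transcript:
    """An entry of the transcriptome map (0-based half-open)."""

    start: int
    end: int
    strand: str
    kind: str  # mRNA | RNA | novel-intergenic | novel-antisense
    genes: tuple[str, ...] = ()
    utr5: int = 0
    utr3: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------


def compute_coverage(alignments: Iterable[AlignmentRecord], n: int,
                     strandedness: str = "fwd") -> StrandCoverage:
    """Accumulate alignment weights into per-strand depth arrays.

    ``strandedness`` maps alignment orientation to transcribed strand:
    'fwd' keeps it, 'rev' flips it, 'none' pools everything into one track.
    """
    cov = StrandCoverage(n, stranded=strandedness != "none")
    flip = {"+": "-", "-": "+"}
    for a in alignments:
        strand = a.strand if strandedness != "rev" else flip[a.strand]
        end = min(a.pos + a.ref_len, n)
        cov.add(strand if cov.stranded else "+", a.pos, end, a.weight)
    return cov


def coverage_threshold(cov: StrandCoverage, strand: str = "+") -> int:
    """Seed threshold T = max(2, ceil(mean per-nucleotide coverage))."""
    arr = cov.get(strand)
    mu = float(arr.mean()) if arr.size else 0.0
    return max(2, ceil(mu))


def _runs_at_least(mask: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """Maximal True-runs of length >= min_len, as half-open intervals."""
    if not mask.any():
        return []
    padded = np.concatenate([[0], mask.view(np.int8), [0]])
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return [(int(s), int(e)) for s, e in zip(starts, ends) if e - s >= min_len]


def find_novel_seeds(cov: StrandCoverage, annotations: Sequence[GeneAnnotation],
                     w: int, T: float, strand: str) -> list[TranscriptSeed]:
    """Maximal runs of >= w nucleotides with coverage >= T, outside
    same-strand annotated genes."""
    if w < 1 or T < 1:
        raise ValueError("w and T must be >= 1")
    arr = cov.get(strand)
    runs = _runs_at_least(arr >= T, w)
    gene_ivals = [to_internal(g.start, g.stop) for g in annotations
                  if g.strand == strand]
    out = []
    for s, e in runs:
        inside = any(gs <= s and e <= ge for gs, ge in gene_ivals)
        if not inside:
            out.append(TranscriptSeed(start=s, end=e, strand=strand))
    return out


def fit_background(cov: StrandCoverage, annotations: Sequence[GeneAnnotation]
                   ) -> float:
    """Geometric background parameter from antisense coverage over CDS.

    Method of moments: a geometric on {0,1,2,...} with mean mu has success
    probability p = 1/(1+mu).
    """
    flip = {"+": "-", "-": "+"}
    total = 0.0
    length = 0
    for g in annotations:
        if g.kind != "CDS":
            continue
        s, e = to_internal(g.start, g.stop)
        anti = cov.get(flip[g.strand])
        total += float(anti[s:e].sum())
        length += e - s
    if length == 0:
        logger.warning("no CDS annotations; background from sub-threshold coverage")
        pooled = np.concatenate([arr for _, arr in cov.tracks()])
        T = max(2, ceil(pooled.mean())) if pooled.size else 2
        low = pooled[pooled < T]
        mu = float(low.mean()) if low.size else 0.0
    else:
        mu = total / length
    return 1.0 / (1.0 + mu)


def extension_decision(x: float, lam: float, p_bg: float, step: int) -> bool:
    """Extend iff the window count is at least as likely under the transcript
    Poisson as under the background (sum of ``step`` iid geometrics)."""
    if lam <= 0:
        return False
    xi = int(round(x))
    p_sig = stats.poisson.pmf(xi, step * lam)
    p_back = stats.nbinom.pmf(xi, step, p_bg)
    return bool(p_sig >= p_back)


def extend_seed(seed: TranscriptSeed, cov: StrandCoverage, model: ExtensionModel,
                step: int = 5, lower_bound: int = 0,
                upper_bound: int | None = None) -> TranscriptSeed:
    """Extend a seed outward in windows of ``step`` nt until the background
    class wins, then trim extended zero-coverage flanks.

    The Poisson rate is fitted once from the original seed and not refitted
    during extension.  Extension halts at ``lower_bound``/``upper_bound``
    (genome edge or an adjacent seed).
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    arr = cov.get(seed.strand)
    n = len(arr)
    if upper_bound is None:
        upper_bound = n
    start, end = seed.start, seed.end
    if model.lam > 0:
        pos = start
        while pos > lower_bound:
            a = max(lower_bound, pos - step)
            x = float(arr[a:pos].sum())
            if not extension_decision(x, model.lam, model.p_bg, pos - a):
                break
            pos = a
        start = pos
        pos = end
        while pos < upper_bound:
            b = min(upper_bound, pos + step)
            x = float(arr[pos:b].sum())
            if not extension_decision(x, model.lam, model.p_bg, b - pos):
                break
            pos = b
        end = pos
    # trim zero-coverage positions gained by extension (never inside the core)
    while start < seed.core_start and arr[start] == 0:
        start += 1
    while end > seed.core_end and arr[end - 1] == 0:
        end -= 1
    return replace(seed, start=start, end=end)


def merge_seeds(seeds: Sequence[TranscriptSeed], cov: StrandCoverage,
                merge_ratio: float = 2.0) -> list[TranscriptSeed]:
    """Merge overlapping seeds always; merge abutting seeds when their mean
    coverages are within ``merge_ratio`` of each other.  Applied left to
    right until a fixpoint."""
    if not seeds:
        return []
    arr = cov.get(seeds[0].strand)

    def mean_cov(s: TranscriptSeed) -> float:
        span = arr[s.start:s.end]
        return float(span.mean()) if span.size else 0.0

    work = sorted(seeds, key=lambda s: (s.start, s.end))
    changed = True
    while changed:
        changed = False
        out: list[TranscriptSeed] = []
        for s in work:
            if not out:
                out.append(s)
                continue
            prev = out[-1]
            overlap = s.start < prev.end
            abut = s.start == prev.end
            do_merge = overlap
            if abut and not overlap:
                m1, m2 = mean_cov(prev), mean_cov(s)
                if m1 > 0 and m2 > 0 and max(m1, m2) / min(m1, m2) <= merge_ratio:
                    do_merge = True
            if do_merge:
                out[-1] = TranscriptSeed(
                    start=prev.start, end=max(prev.end, s.end), strand=prev.strand,
                    origin=prev.origin + s.origin,
                    core_start=min(prev.core_start, s.core_start),
                    core_end=max(prev.core_end, s.core_end))
                changed = True
            else:
                out.append(s)
        work = out
    return work


def _classify_novel(seed: TranscriptSeed, annotations: Sequence[GeneAnnotation]
                    ) -> str:
    """Novel transcripts are antisense when >= 50% of their span overlaps an
    opposite-strand annotated gene, intergenic otherwise."""
    span = seed.end - seed.start
    if span <= 0:
        return "novel-intergenic"
    mask = np.zeros(span, dtype=bool)
    for g in annotations:
        if g.strand == seed.strand:
            continue
        gs, ge = to_internal(g.start, g.stop)
        a, b = max(gs, seed.start), min(ge, seed.end)
        if a < b:
            mask[a - seed.start:b - seed.start] = True
    return "novel-antisense" if mask.sum() >= 0.5 * span else "novel-intergenic"


def build_transcriptome_map(cov: StrandCoverage,
                            annotations: Sequence[GeneAnnotation],
                            config: RunConfig | None = None) -> list[Transcript]:
    """Full map: seed, extend, merge and classify on both strands."""
    if config is None:
        config = RunConfig()
    gene_by_id = {g.locus_id: g for g in annotations}
    p_bg = fit_background(cov, annotations)
    transcripts: list[Transcript] = []
    for strand in "+-":
        arr = cov.get(strand)
        T = coverage_threshold(cov, strand)
        seeds = []
        for g in annotations:
            if g.strand != strand:
                continue
            s, e = to_internal(g.start, g.stop)
            seeds.append(TranscriptSeed(start=s, end=e, strand=strand,
                                        origin=(g.locus_id,)))
        seeds += find_novel_seeds(cov, annotations, config.seed_min_len, T, strand)
        seeds.sort(key=lambda s: (s.start, s.end))
        # extension bounds come from the un-extended neighbours
        extended = []
        for i, seed in enumerate(seeds):
            lo = max((s.end for s in seeds[:i] if s.end <= seed.start), default=0)
            hi = min((s.start for s in seeds[i + 1:] if s.start >= seed.end),
                     default=cov.n)
            span = arr[seed.start:seed.end]
            lam = float(span.mean()) if span.size else 0.0
            model = ExtensionModel(lam=lam, p_bg=p_bg) if lam > 0 else None
            if model is None:
                extended.append(seed)
                continue
            extended.append(extend_seed(seed, cov, model,
                                        step=config.extension_step,
                                        lower_bound=lo, upper_bound=hi))
        merged = merge_seeds(extended, cov, config.merge_ratio)
        for seed in merged:
            members = tuple(seed.origin)
            if members:
                genes = [gene_by_id[gid] for gid in members]
                kind = "mRNA" if any(g.kind == "CDS" for g in genes) else "RNA"
                gs = min(to_internal(g.start, g.stop)[0] for g in genes)
                ge = max(to_internal(g.start, g.stop)[1] for g in genes)
                if strand == "+":
                    utr5, utr3 = gs - seed.start, seed.end - ge
                else:
                    utr5, utr3 = seed.end - ge, gs - seed.start
                transcripts.append(Transcript(
                    start=seed.start, end=seed.end, strand=strand, kind=kind,
                    genes=members, utr5=max(0, utr5), utr3=max(0, utr3)))
            else:
                kind = _classify_novel(seed, annotations)
                transcripts.append(Transcript(start=seed.start, end=seed.end,
                                              strand=strand, kind=kind))
    transcripts.sort(key=lambda t: (t.start, t.end, t.strand))
    return transcripts
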