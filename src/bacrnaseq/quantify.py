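"""Transcript quantification and upper-quartile normalization.

A read contributes its alignment weight to every transcript on the matching
strand whose span contains the read's midpoint.  Per-sample counts are
normalized by the upper quartile of non-zero gene counts, which is robust
to a handful of dominant transcripts; the expression measure divides the
count by gene length (in kb) and the upper quartile, times a constant K.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import ceil
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gmean

from .align import AlignmentRecord
from .formats_io import NoExpressedGenes
from .transcriptome import Transcript

logger = logging.getLogger("bacrnaseq")


@dataclass
class CountTable:
    """Transcripts x samples fractional read counts."""

    counts: pd.DataFrame  # index: transcript ids, columns: sample names
    lengths: pd.Series  # transcript length in nt
    totals: pd.Series  # aligned reads per sample (weighted)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


def count_reads(alignments: Iterable[AlignmentRecord],
                transcripts: Sequence[Transcript],
                stranded: bool = True) -> np.ndarray:
    """Midpoint-assignment counts of one sample against a transcript map.

    Returns an array parallel to ``transcripts``.  With ``stranded=False``
    strand is ignored in the assignment.
    """
    counts = np.zeros(len(transcripts))
    mids: dict[str, list[tuple[float, float]]] = {"+": [], "-": []}
    for a in alignments:
        mid = a.pos + a.ref_len // 2
        mids[a.strand].append((mid, a.weight))
    prepared = {}
    for strand, pairs in mids.items():
        if pairs:
            arr = np.array(sorted(pairs))
            prepared[strand] = (arr[:, 0], np.concatenate([[0.0], np.cumsum(arr[:, 1])]))
    for i, t in enumerate(transcripts):
        strands = [t.strand] if stranded else ["+", "-"]
        for strand in strands:
            if strand not in prepared:
                continue
            pos, cum = prepared[strand]
            lo = np.searchsorted(pos, t.start, side="left")
            hi = np.searchsorted(pos, t.end - 1, side="right")
            counts[i] += cum[hi] - cum[lo]
    return counts


def build_count_table(sample_alignments: Mapping[str, Sequence[AlignmentRecord]],
                      transcripts: Sequence[Transcript],
                      stranded: bool = True) -> CountTable:
    ids = [f"T{i + 1:05d}" if not t.genes else "+".join(t.genes)
           for i, t in enumerate(transcripts)]
    data = {}
    totals = {}
    for sample, alns in sample_alignments.items():
        data[sample] = count_reads(alns, transcripts, stranded=stranded)
        totals[sample] = float(sum(a.weight for a in alns))
    counts = pd.DataFrame(data, index=ids)
    lengths = pd.Series([t.length for t in transcripts], index=ids)
    return CountTable(counts=counts, lengths=lengths, totals=pd.Series(totals))


def upper_quartile(values: np.ndarray | Sequence[float]) -> float:
    """Upper quartile of the non-zero values: the order statistic at rank
    ceil(0.75 * n') among the n' positive values (no interpolation)."""
    v = np.asarray(values, dtype=float)
    pos = np.sort(v[v > 0])
    if pos.size == 0:
        raise NoExpressedGenes("all genes have zero counts")
    rank = ceil(0.75 * pos.size)
    return float(pos[rank - 1])


def expression(count: float, length_nt: float, uq: float, k: float = 1000.0
               ) -> float:
    """Upper-quartile-normalized, length-normalized expression."""
    if length_nt <= 0 or uq <= 0:
        raise ValueError("length and upper quartile must be positive")
    return k * count / ((length_nt / 1000.0) * uq)


def normalization_factors(table: CountTable) -> pd.Series:
    """Per-sample scaling factors: UQ_s / geometric mean of all UQs.

    Dividing raw counts by the factor puts samples on a common scale."""
    uqs = {s: upper_quartile(table.counts[s].to_numpy()) for s in table.samples}
    uq_arr = np.array(list(uqs.values()))
    g = float(gmean(uq_arr))
    return pd.Series({s: u / g for s, u in uqs.items()})


def normalized_counts(table: CountTable) -> pd.DataFrame:
    factors = normalization_factors(table)
    return table.counts / factors


def expression_table(table: CountTable, k: float = 1000.0) -> pd.DataFrame:
    """Expression matrix (transcripts x samples)."""
    out = {}
    for s in table.samples:
        col = table.counts[s].to_numpy()
        uq = upper_quartile(col)
        out[s] = k * col / ((table.lengths.to_numpy() / 1000.0) * uq)
    return pd.DataFrame(out, index=table.counts.index)
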