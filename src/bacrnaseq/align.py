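"""Read alignment against a bacterial reference genome.

Exact matches are found with an FM-index (Burrows-Wheeler transform plus
backward search).  Reads that do not match exactly go through seed-and-extend:
the read is partitioned into non-overlapping seeds so that, by pigeonhole,
any alignment within the edit budget leaves at least one seed error-free;
each seed hit nominates a genomic window which is scored with a banded,
quality-aware dynamic program.

Scoring: matches cost 0, a mismatch costs min(Phred quality of the read
base, 30), an inserted or deleted base costs 30.  The optimum is the
placement of minimum total penalty subject to at most k edits, where
k = ceil(k_frac * m) and m is the read length (k_frac = 0.15 by default).
When several placements are co-optimal all are reported, each carrying
weight 1/n_optimal; alignment is therefore fully deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import ceil
from typing import Iterable, Sequence

import numpy as np
from numba import njit

from .formats_io import GenomeRecord, ReadRecord, RunConfig

logger = logging.getLogger("bacrnaseq")

# symbol codes; sentinel 0 is lexicographically smallest
_ALPHABET = "$ACGNT"
_CODE = {c: i for i, c in enumerate(_ALPHABET)}
_N_CODE = _CODE["N"]
_NSYM = len(_ALPHABET)
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

MISMATCH_CAP = 30
INDEL_PENALTY = 30
_INF = np.int32(2 ** 30)


def encode(seq: str) -> np.ndarray:
    """Map a nucleotide string to the internal symbol codes."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    lut = np.zeros(128, dtype=np.int8)
    for c, i in _CODE.items():
        lut[ord(c)] = i
    return lut[arr]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _suffix_array(codes: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (O(n log^2 n), numpy-vectorized)."""
    n = len(codes)
    rank = codes.astype(np.int64)
    k = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        new_rank = np.empty(n, dtype=np.int64)
        r_o = rank[order]
        k_o = key2[order]
        changed = np.empty(n, dtype=bool)
        changed[0] = False
        changed[1:] = (r_o[1:] != r_o[:-1]) | (k_o[1:] != k_o[:-1])
        new_rank[order] = np.cumsum(changed)
        rank = new_rank
        if rank[order[-1]] == n - 1:
            return order.astype(np.int64)
        k *= 2


class FMIndex:
    """FM-index of a genome: BWT, cumulative counts C, occurrence table and
    sampled suffix-array entries.

    ``occ_rate`` controls occurrence-table sampling (1 = dense, which enables
    vectorized batch search); ``sa_rate`` controls suffix-array sampling for
    :meth:`locate` (positions are recovered by LF-walking to a sampled row).
    """

    def __init__(self, text: str, occ_rate: int = 1, sa_rate: int = 4):
        if not text:
            raise ValueError("cannot index an empty text")
        if "$" in text:
            raise ValueError("text must not contain the sentinel symbol")
        self.text_len = len(text)
        # nucleotide texts use the fixed DNA alphabet (so that batch search
        # can share the module-level encoder); anything else gets an
        # alphabet derived from the text
        if set(text) <= set("ACGNT"):
            self.alphabet = _ALPHABET
        else:
            self.alphabet = "$" + "".join(sorted(set(text)))
        self._code = {c: i for i, c in enumerate(self.alphabet)}
        self._nsym = len(self.alphabet)
        codes = np.concatenate([self._encode(text), np.zeros(1, dtype=np.int16)])
        n = len(codes)
        sa = _suffix_array(codes)
        self.bwt = codes[sa - 1]  # sa-1 == -1 wraps to the sentinel, as required
        counts = np.bincount(codes, minlength=self._nsym)
        self.C = np.concatenate([[0], np.cumsum(counts)])[:self._nsym].astype(np.int64)
        self.occ_rate = int(occ_rate)
        self.sa_rate = int(sa_rate)
        # occurrence table: occ[i, c] = # of c in bwt[:i*occ_rate]
        onehot = np.zeros((n + 1, self._nsym), dtype=np.int64)
        onehot[1:, :] = (self.bwt[:, None] == np.arange(self._nsym)[None, :])
        full_occ = np.cumsum(onehot, axis=0)
        if self.occ_rate == 1:
            self._occ = full_occ
        else:
            self._occ = full_occ[:: self.occ_rate].copy()
        # suffix-array samples at text positions divisible by sa_rate
        self.sa_samples = np.where(sa % self.sa_rate == 0, sa, -1)
        del full_occ

    def _encode(self, s: str) -> np.ndarray:
        out = np.empty(len(s), dtype=np.int16)
        for i, c in enumerate(s):
            out[i] = self._code.get(c, -1)
        return out

    @property
    def bwt_string(self) -> str:
        """The Burrows-Wheeler transform as text (sentinel rendered as $)."""
        return "".join(self.alphabet[c] for c in self.bwt)

    # -- rank / LF ---------------------------------------------------------

    def rank(self, c: int, i) -> np.ndarray | int:
        """Number of occurrences of symbol ``c`` in bwt[:i]."""
        if self.occ_rate == 1:
            return self._occ[i, c]
        i = np.asarray(i)
        blk = i // self.occ_rate
        base = self._occ[blk, c]
        if i.ndim == 0:
            lo = int(blk) * self.occ_rate
            return int(base) + int(np.count_nonzero(self.bwt[lo:int(i)] == c))
        out = np.empty(i.shape, dtype=np.int64)
        flat_i = i.ravel()
        flat_b = np.asarray(base).ravel()
        for j in range(flat_i.size):
            lo = (flat_i[j] // self.occ_rate) * self.occ_rate
            out.ravel()[j] = flat_b[j] + np.count_nonzero(
                self.bwt[lo:flat_i[j]] == c)
        return out

    def _lf(self, row: int) -> int:
        c = self.bwt[row]
        return int(self.C[c]) + int(self.rank(int(c), row))

    # -- search ------------------------------------------------------------

    def search(self, pattern: str) -> tuple[int, int]:
        """Backward search; returns the half-open BWT row range [lo, hi)."""
        if not pattern:
            raise ValueError("empty pattern")
        codes = self._encode(pattern)
        if np.any(codes < 0):
            return 0, 0  # symbol absent from the indexed text
        if "N" in self._code and np.any(codes == self._code["N"]):
            return 0, 0  # N never matches
        lo, hi = 0, len(self.bwt)
        for c in codes[::-1]:
            c = int(c)
            lo = int(self.C[c]) + int(self.rank(c, lo))
            hi = int(self.C[c]) + int(self.rank(c, hi))
            if lo >= hi:
                return 0, 0
        return lo, hi

    def count(self, pattern: str) -> int:
        lo, hi = self.search(pattern)
        return hi - lo

    def locate_range(self, lo: int, hi: int) -> np.ndarray:
        """Genome offsets for BWT rows [lo, hi), sorted ascending."""
        out = np.empty(hi - lo, dtype=np.int64)
        for i, row in enumerate(range(lo, hi)):
            steps = 0
            r = row
            while self.sa_samples[r] < 0:
                r = self._lf(r)
                steps += 1
            out[i] = self.sa_samples[r] + steps
        out.sort()
        return out

    def locate(self, pattern: str) -> np.ndarray:
        lo, hi = self.search(pattern)
        return self.locate_range(lo, hi)

    def batch_search(self, patterns: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Backward search for many equal-length patterns at once.

        ``patterns`` is an (n_patterns, length) code matrix.  Requires a
        dense occurrence table (occ_rate == 1).  Patterns containing N
        report an empty range.
        """
        if self.occ_rate != 1:
            raise ValueError("batch search requires a dense occurrence table")
        npat, m = patterns.shape
        lo = np.zeros(npat, dtype=np.int64)
        hi = np.full(npat, len(self.bwt), dtype=np.int64)
        alive = ~np.any(patterns == _N_CODE, axis=1)
        lo[~alive] = hi[~alive] = 0
        for col in range(m - 1, -1, -1):
            if not alive.any():
                break
            c = patterns[alive, col].astype(np.int64)
            base = self.C[c]
            lo_a = base + self._occ[lo[alive], c]
            hi_a = base + self._occ[hi[alive], c]
            lo[alive] = lo_a
            hi[alive] = hi_a
            dead = lo_a >= hi_a
            if dead.any():
                idx = np.flatnonzero(alive)[dead]
                lo[idx] = hi[idx] = 0
                alive[idx] = False
        return lo, hi


def build_fm_index(genome: GenomeRecord, occ_rate: int = 1, sa_rate: int = 4
                   ) -> FMIndex:
    """Build the FM-index of a genome sequence."""
    return FMIndex(genome.seq, occ_rate=occ_rate, sa_rate=sa_rate)


def align_exact(index: FMIndex, pattern: str) -> set[int]:
    """All genome offsets where ``pattern`` occurs exactly."""
    return set(int(p) for p in index.locate(pattern))


# ---------------------------------------------------------------------------
# banded quality-aware dynamic program


@njit(cache=True)
def _banded_dp(read: np.ndarray, quals: np.ndarray, window: np.ndarray,
               k: int, inf: np.int32):  # pragma: no cover - numba
    m = read.shape[0]
    wlen = window.shape[0]
    lo_off = -k
    hi_off = (wlen - m) + k
    pen = np.full((m + 1, wlen + 1), inf, dtype=np.int32)
    eds = np.full((m + 1, wlen + 1), inf, dtype=np.int32)
    sta = np.full((m + 1, wlen + 1), inf, dtype=np.int32)
    for j in range(wlen + 1):
        pen[0, j] = 0
        eds[0, j] = 0
        sta[0, j] = j  # free leading window skip: alignment starts at offset j
    for i in range(1, m + 1):
        q = quals[i - 1]
        mm = q if q < MISMATCH_CAP else MISMATCH_CAP
        jmin = i + lo_off
        if jmin < 0:
            jmin = 0
        jmax = i + hi_off
        if jmax > wlen:
            jmax = wlen
        for j in range(jmin, jmax + 1):
            bp = inf
            be = inf
            bs = inf
            if j > 0 and pen[i - 1, j - 1] < inf:
                same = window[j - 1] == read[i - 1]
                is_n = window[j - 1] == 4 or read[i - 1] == 4
                cost = 0 if (same and not is_n) else mm
                e = 0 if (same and not is_n) else 1
                p2 = pen[i - 1, j - 1] + cost
                e2 = eds[i - 1, j - 1] + e
                s2 = sta[i - 1, j - 1]
                if p2 < bp or (p2 == bp and (e2 < be or (e2 == be and s2 < bs))):
                    bp, be, bs = p2, e2, s2
            if pen[i - 1, j] < inf:  # read base inserted (absent from window)
                p2 = pen[i - 1, j] + INDEL_PENALTY
                e2 = eds[i - 1, j] + 1
                s2 = sta[i - 1, j]
                if p2 < bp or (p2 == bp and (e2 < be or (e2 == be and s2 < bs))):
                    bp, be, bs = p2, e2, s2
            if j > 0 and pen[i, j - 1] < inf:  # window base deleted
                p2 = pen[i, j - 1] + INDEL_PENALTY
                e2 = eds[i, j - 1] + 1
                s2 = sta[i, j - 1]
                if p2 < bp or (p2 == bp and (e2 < be or (e2 == be and s2 < bs))):
                    bp, be, bs = p2, e2, s2
            pen[i, j] = bp
            eds[i, j] = be
            sta[i, j] = bs
    # free trailing window skip: best cell in the last row
    bp = inf
    be = inf
    bs = inf
    bj = -1
    for j in range(wlen + 1):
        if pen[m, j] >= inf:
            continue
        p2 = pen[m, j]
        e2 = eds[m, j]
        s2 = sta[m, j]
        better = False
        if p2 < bp:
            better = True
        elif p2 == bp:
            if e2 < be:
                better = True
            elif e2 == be and s2 < bs:
                better = True
        if better:
            bp, be, bs, bj = p2, e2, s2, j
    return bp, be, bs, bj


def banded_align(read: ReadRecord, window: str, k: int
                 ) -> tuple[int, int, int] | None:
    """Best quality-aware alignment of ``read`` within ``window``.

    Returns ``(penalty, edits, offset)`` where ``offset`` is the leftmost
    window offset of the aligned region among co-optimal placements, or
    ``None`` if no alignment with at most ``k`` edits exists.  The dynamic
    program only fills entries within ``k`` of the alignment diagonal.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    res = _banded_dp(encode(read.seq).astype(np.int8),
                     np.minimum(read.quals, MISMATCH_CAP).astype(np.int32),
                     encode(window).astype(np.int8), int(k), _INF)
    penalty, edits, start, end = res
    if penalty >= int(_INF) or edits > k:
        return None
    return int(penalty), int(edits), int(start)


def _banded_span(read: ReadRecord, window: str, k: int):
    """Like :func:`banded_align` but also returns the window end offset."""
    res = _banded_dp(encode(read.seq).astype(np.int8),
                     np.minimum(read.quals, MISMATCH_CAP).astype(np.int32),
                     encode(window).astype(np.int8), int(k), _INF)
    penalty, edits, start, end = res
    if penalty >= int(_INF) or edits > k:
        return None
    return int(penalty), int(edits), int(start), int(end)


# ---------------------------------------------------------------------------
# read-level alignment


@dataclass
class AlignmentRecord:
    """One placement of a read on the genome.

    ``pos`` is the 0-based offset of the leftmost aligned genome base,
    ``strand`` the genome strand the read sequence matched ('+' as given,
    '-' via reverse complement), ``ref_len`` the genomic span consumed,
    and ``weight`` = 1/n_optimal distributes multi-mapped reads evenly
    over their co-optimal placements.
    """

    read_id: str
    pos: int
    strand: str
    penalty: int
    edits: int
    n_optimal: int
    ref_len: int

    @property
    def weight(self) -> float:
        return 1.0 / self.n_optimal


@dataclass
class AlignmentStats:
    total_reads: int = 0
    aligned_reads: int = 0

    @property
    def fraction_aligned(self) -> float:
        return self.aligned_reads / self.total_reads if self.total_reads else 0.0


def _seed_partition(m: int, s: int) -> list[tuple[int, int]]:
    """Split [0, m) into s contiguous, non-overlapping, near-equal chunks."""
    bounds = np.linspace(0, m, s + 1).astype(int)
    return [(int(bounds[i]), int(bounds[i + 1])) for i in range(s)]


_MIN_SEED_LEN = 4  # seeds shorter than this nominate too many spurious loci


def _candidate_windows(index: FMIndex, seq: str, m: int, k: int, s: int
                       ) -> set[int]:
    """Window start offsets nominated by exact matches of the s seeds."""
    cands: set[int] = set()
    for off, end in _seed_partition(m, s):
        if end - off < 1:
            continue
        seed = seq[off:end]
        lo, hi = index.search(seed)
        if hi - lo > 200:  # hyper-repetitive seed: skip, rescue at a later level
            continue
        for p in index.locate_range(lo, hi):
            ws = int(p) - off - k
            cands.add(ws)
    return cands


def align_read(index: FMIndex, genome: GenomeRecord, read: ReadRecord,
               config: RunConfig) -> list[AlignmentRecord]:
    """Align one read (both orientations); returns all co-optimal placements."""
    m = len(read.seq)
    if m < config.min_read_len:
        return []
    k = ceil(config.k_frac * m)
    orientations = [("+", read.seq, read.quals)]
    rc = reverse_complement(read.seq)
    orientations.append(("-", rc, read.quals[::-1]))

    # exact full-length match first
    exact_hits: list[tuple[int, str]] = []
    for strand, seq, _ in orientations:
        lo, hi = index.search(seq) if "N" not in seq else (0, 0)
        for p in index.locate_range(lo, hi):
            exact_hits.append((int(p), strand))
    if exact_hits:
        n = len(exact_hits)
        return [AlignmentRecord(read.id, p, st, 0, 0, n, m)
                for p, st in sorted(exact_hits)]

    if k == 0:
        return []

    # seed-and-extend with escalating seed counts; level s guarantees that
    # every alignment with <= s-1 edits is among the candidates (pigeonhole)
    min_edit_cost = int(min(MISMATCH_CAP, int(read.quals.min()) if m else MISMATCH_CAP))
    min_edit_cost = max(min_edit_cost, 1)
    best_penalty = None
    best: list[tuple[int, str, int, int, int]] = []  # pos, strand, pen, edits, ref_len
    seen: set[tuple[int, str]] = set()
    for s in range(2, k + 2):
        if m // s < _MIN_SEED_LEN:
            break
        for strand, seq, quals in orientations:
            rec = ReadRecord(read.id, seq, quals)
            for ws in sorted(_candidate_windows(index, seq, m, k, s)):
                a = max(0, ws)
                b = min(genome.n, ws + m + 2 * k)
                if b - a < m - k:
                    continue
                if (a, strand) in seen:
                    continue
                seen.add((a, strand))
                r = _banded_span(rec, genome.seq[a:b], k)
                if r is None:
                    continue
                pen, edits, w_start, w_end = r
                pos = a + w_start
                entry = (pos, strand, pen, edits, w_end - w_start)
                if best_penalty is None or pen < best_penalty:
                    best_penalty = pen
                    best = [entry]
                elif pen == best_penalty:
                    best.append(entry)
        # no alignment with >= s edits can beat what we already found
        if best_penalty is not None and best_penalty < s * min_edit_cost:
            break
    if not best:
        return []
    uniq = {}
    for pos, strand, pen, edits, rlen in best:
        uniq[(pos, strand)] = (pen, edits, rlen)
    n = len(uniq)
    return [AlignmentRecord(read.id, pos, strand, pen, edits, n, rlen)
            for (pos, strand), (pen, edits, rlen) in sorted(uniq.items())]


def align_all(reads: Sequence[ReadRecord], genome: GenomeRecord,
              config: RunConfig, index: FMIndex | None = None,
              ) -> tuple[list[AlignmentRecord], AlignmentStats]:
    """Align a collection of reads; deterministic regardless of batching.

    Reads of equal length are exact-matched in vectorized batches through
    the FM-index; only reads without a perfect match fall back to the
    per-read seed-and-extend path.
    """
    if index is None:
        index = build_fm_index(genome)
    stats = AlignmentStats(total_reads=len(reads))
    out: list[AlignmentRecord] = []
    if not reads:
        return out, stats

    by_len: dict[int, list[int]] = {}
    for i, r in enumerate(reads):
        by_len.setdefault(len(r.seq), []).append(i)

    pending: list[int] = []
    for m, idxs in sorted(by_len.items()):
        if m < config.min_read_len:
            continue
        fwd = np.stack([encode(reads[i].seq) for i in idxs])
        rev = np.stack([encode(reverse_complement(reads[i].seq)) for i in idxs])
        flo, fhi = index.batch_search(fwd)
        rlo, rhi = index.batch_search(rev)
        for j, i in enumerate(idxs):
            hits: list[tuple[int, str]] = []
            if fhi[j] > flo[j]:
                hits += [(int(p), "+") for p in index.locate_range(int(flo[j]), int(fhi[j]))]
            if rhi[j] > rlo[j]:
                hits += [(int(p), "-") for p in index.locate_range(int(rlo[j]), int(rhi[j]))]
            if hits:
                n = len(hits)
                out.extend(AlignmentRecord(reads[i].id, p, st, 0, 0, n, m)
                           for p, st in sorted(hits))
                stats.aligned_reads += 1
            else:
                pending.append(i)

    for i in sorted(pending):
        recs = align_read(index, genome, reads[i], config)
        if recs:
            stats.aligned_reads += 1
            out.extend(recs)
    return out, stats


# ---------------------------------------------------------------------------
# optional SAM export


def _cigar(read: ReadRecord, genome: GenomeRecord, rec: AlignmentRecord) -> str:
    """Reconstruct a CIGAR string by re-running an unbanded DP with traceback."""
    seq = read.seq if rec.strand == "+" else reverse_complement(read.seq)
    quals = read.quals if rec.strand == "+" else read.quals[::-1]
    ref = genome.seq[rec.pos:rec.pos + rec.ref_len]
    m, w = len(seq), len(ref)
    pen = np.full((m + 1, w + 1), np.inf)
    pen[0, 0] = 0
    move = np.zeros((m + 1, w + 1), dtype=np.int8)
    for i in range(1, m + 1):
        pen[i, 0] = pen[i - 1, 0] + INDEL_PENALTY
        move[i, 0] = 1
    for j in range(1, w + 1):
        pen[0, j] = pen[0, j - 1] + INDEL_PENALTY
        move[0, j] = 2
    for i in range(1, m + 1):
        mm = min(int(quals[i - 1]), MISMATCH_CAP)
        for j in range(1, w + 1):
            match = seq[i - 1] == ref[j - 1] and seq[i - 1] != "N"
            d = pen[i - 1, j - 1] + (0 if match else mm)
            u = pen[i - 1, j] + INDEL_PENALTY
            l = pen[i, j - 1] + INDEL_PENALTY
            pen[i, j] = min(d, u, l)
            move[i, j] = 0 if pen[i, j] == d else (1 if pen[i, j] == u else 2)
    ops = []
    i, j = m, w
    while i > 0 or j > 0:
        mv = move[i, j]
        if mv == 0:
            ops.append("M")
            i, j = i - 1, j - 1
        elif mv == 1:
            ops.append("I")
            i -= 1
        else:
            ops.append("D")
            j -= 1
    ops.reverse()
    out = []
    for op in ops:
        if out and out[-1][1] == op:
            out[-1][0] += 1
        else:
            out.append([1, op])
    return "".join(f"{c}{op}" for c, op in out)


def write_sam(path, reads: Sequence[ReadRecord], alignments: Sequence[AlignmentRecord],
              genome: GenomeRecord) -> None:
    """Minimal single-reference SAM export; unmapped reads get flag 4."""
    by_read: dict[str, list[AlignmentRecord]] = {}
    for a in alignments:
        by_read.setdefault(a.read_id, []).append(a)
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        fh.write(f"@SQ\tSN:{genome.id}\tLN:{genome.n}\n")
        fh.write("@PG\tID:bacrnaseq\tPN:bacrnaseq\n")
        for read in reads:
            recs = by_read.get(read.id)
            qual_str = "".join(chr(int(q) + 33) for q in read.quals)
            if not recs:
                fh.write(f"{read.id}\t4\t*\t0\t0\t*\t*\t0\t0\t{read.seq}\t{qual_str}\n")
                continue
            for i, rec in enumerate(recs):
                flag = 0 if rec.strand == "+" else 16
                if i > 0:
                    flag |= 256
                seq = read.seq if rec.strand == "+" else reverse_complement(read.seq)
                q = qual_str if rec.strand == "+" else qual_str[::-1]
                cigar = (f"{len(read.seq)}M" if rec.ref_len == len(read.seq)
                         else _cigar(read, genome, rec))
                fh.write(f"{read.id}\t{flag}\t{genome.id}\t{rec.pos + 1}\t255\t"
                         f"{cigar}\t*\t0\t0\t{seq}\t{q}\tNM:i:{rec.edits}\n")
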