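"""Aligner: FM-index vs naive scan, banded DP vs full DP, seed-and-extend."""

import numpy as np
import pytest

from bacrnaseq.align import (AlignmentRecord, FMIndex, align_all, align_exact,
                             align_read, banded_align, build_fm_index,
                             reverse_complement, write_sam, MISMATCH_CAP,
                             INDEL_PENALTY)
from bacrnaseq.formats_io import GenomeRecord, ReadRecord, RunConfig
from bacrnaseq.simdata import simulate_genome

from conftest import make_read


def naive_occurrences(text: str, pattern: str) -> list[int]:
    out, start = [], 0
    while True:
        i = text.find(pattern, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


def full_dp(read: ReadRecord, window: str):
    """Unbanded fitting alignment minimizing (penalty, edits); oracle for the
    banded dynamic program."""
    m, w = len(read.seq), len(window)
    INF = 10 ** 9
    pen = np.full((m + 1, w + 1), INF)
    eds = np.full((m + 1, w + 1), INF)
    pen[0, :], eds[0, :] = 0, 0
    for i in range(1, m + 1):
        mm = min(int(read.quals[i - 1]), MISMATCH_CAP)
        for j in range(0, w + 1):
            cands = []
            if j > 0:
                match = read.seq[i - 1] == window[j - 1] and read.seq[i - 1] != "N"
                cands.append((pen[i - 1, j - 1] + (0 if match else mm),
                              eds[i - 1, j - 1] + (0 if match else 1)))
            cands.append((pen[i - 1, j] + INDEL_PENALTY, eds[i - 1, j] + 1))
            if j > 0:
                cands.append((pen[i, j - 1] + INDEL_PENALTY, eds[i, j - 1] + 1))
            pen[i, j], eds[i, j] = min(cands)
    best = min((pen[m, j], eds[m, j]) for j in range(w + 1))
    return int(best[0]), int(best[1])


class TestFMIndex:
    def test_bwt_of_banana(self):
        # brute-force check: sorted rotations of 'banana$' end with 'annb$aa'
        assert FMIndex("banana").bwt_string == "annb$aa"

    def test_single_symbol_text(self):
        assert FMIndex("A").bwt_string == "A$"

    def test_search_equals_naive_scan(self, small_genome, rng):
        idx = build_fm_index(small_genome)
        text = small_genome.seq
        for length in (1, 3, 7, 15, 20):
            for _ in range(30):
                start = int(rng.integers(0, len(text) - length))
                pat = text[start:start + length]
                assert sorted(align_exact(idx, pat)) == naive_occurrences(text, pat)
        # patterns absent from the genome
        for _ in range(20):
            pat = "".join(rng.choice(list("ACGT"), size=25))
            assert sorted(align_exact(idx, pat)) == naive_occurrences(text, pat)

    def test_sampled_tables_agree_with_full_suffix_array(self, rng):
        text = "".join(rng.choice(list("ACGT"), size=400))
        dense = FMIndex(text, occ_rate=1, sa_rate=1)
        sparse = FMIndex(text, occ_rate=8, sa_rate=4)
        for _ in range(50):
            i = int(rng.integers(0, len(text) - 6))
            pat = text[i:i + 6]
            assert list(sparse.locate(pat)) == list(dense.locate(pat))

    def test_batch_search_matches_scalar_search(self, small_genome, rng):
        idx = build_fm_index(small_genome)
        pats = [small_genome.seq[i:i + 12]
                for i in rng.integers(0, small_genome.n - 12, size=40)]
        from bacrnaseq.align import encode
        lo, hi = idx.batch_search(np.stack([encode(p) for p in pats]))
        for p, l, h in zip(pats, lo, hi):
            assert (l, h) == idx.search(p)

    def test_n_never_matches(self):
        idx = build_fm_index(GenomeRecord("g", "ACGNACGT"))
        assert align_exact(idx, "ACGN") == set()
        assert align_exact(idx, "CGTA") == set()  # would need genome N to match A

    def test_empty_pattern_rejected(self, small_genome):
        with pytest.raises(ValueError):
            build_fm_index(small_genome).search("")


class TestBandedAlign:
    def test_single_mismatch_costs_capped_quality(self):
        r = make_read("ACGA")
        assert banded_align(r, "ACGT", 1) == (30, 1, 0)

    def test_identity_costs_zero(self):
        r = make_read("ACGT")
        assert banded_align(r, "ACGT", 1) == (0, 0, 0)

    def test_low_quality_mismatch_costs_its_phred(self):
        r = ReadRecord("r", "ACGA", np.array([30, 30, 30, 7]))
        assert banded_align(r, "ACGT", 1)[0] == 7

    def test_failure_when_edits_exceed_k(self):
        r = make_read("AAAA")
        assert banded_align(r, "CCCC", 2) is None

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError):
            banded_align(make_read("ACGT"), "ACGT", -1)

    def test_leftmost_offset_reported(self):
        # window contains the read twice; leftmost placement wins
        r = make_read("ACG")
        pen, ed, off = banded_align(r, "ACGACG", 1)
        assert (pen, ed, off) == (0, 0, 0)

    def test_agrees_with_full_dp_on_random_triples(self, rng):
        for _ in range(40):
            m = int(rng.integers(10, 30))
            k = int(rng.integers(1, max(2, m // 5)))
            window = "".join(rng.choice(list("ACGT"), size=m + 2 * k))
            # read derived from the window center with a few mutations
            seq = list(window[k:k + m])
            for _ in range(int(rng.integers(0, k + 1))):
                j = int(rng.integers(m))
                seq[j] = rng.choice(list("ACGT"))
            read = ReadRecord("r", "".join(seq),
                              rng.integers(2, 41, size=m).astype(np.int16))
            res = banded_align(read, window, k)
            fp, fe = full_dp(read, window)
            if fe <= k:
                assert res is not None
                assert res[0] == fp  # same optimal penalty
            elif res is not None:
                assert res[0] >= fp  # banded never beats the full optimum


class TestAlignRead:
    def test_unique_exact_match(self, small_genome, config):
        idx = build_fm_index(small_genome)
        read = make_read(small_genome.seq[500:560])
        recs = align_read(idx, small_genome, read, config)
        assert len(recs) == 1
        assert (recs[0].pos, recs[0].strand, recs[0].edits) == (500, "+", 0)
        assert recs[0].weight == 1.0

    def test_two_loci_split_weight(self, config):
        core = "ACGTACGTACGTACGTACGT"
        genome = GenomeRecord("g", core + "TTTTTTTTTT" + core)
        idx = build_fm_index(genome)
        recs = align_read(idx, genome, make_read(core), config)
        # palindromic-free repeat: expect the two planted forward copies
        fwd = [r for r in recs if r.strand == "+"]
        assert {r.pos for r in fwd} == {0, 30}
        assert all(r.weight == pytest.approx(1 / len(recs)) for r in recs)
        assert sum(r.weight for r in recs) == pytest.approx(1.0)

    def test_reverse_complement_read_maps_minus_strand(self, small_genome, config):
        idx = build_fm_index(small_genome)
        read = make_read(reverse_complement(small_genome.seq[100:160]))
        recs = align_read(idx, small_genome, read, config)
        assert len(recs) == 1 and recs[0].strand == "-" and recs[0].pos == 100

    def test_short_read_unaligned(self, small_genome, config):
        idx = build_fm_index(small_genome)
        recs = align_read(idx, small_genome, make_read(small_genome.seq[0:8]), config)
        assert recs == []

    def test_planted_mismatch_recovered(self, config, rng):
        genome = simulate_genome(10000, seed=rng)
        idx = build_fm_index(genome)
        hits = 0
        for i in range(50):
            pos = int(rng.integers(0, genome.n - 60))
            seq = list(genome.seq[pos:pos + 60])
            j = int(rng.integers(60))
            seq[j] = [b for b in "ACGT" if b != seq[j]][int(rng.integers(3))]
            recs = align_read(idx, genome, make_read("".join(seq), rid=f"r{i}"), config)
            if any(r.pos == pos and r.strand == "+" and r.edits == 1 for r in recs):
                hits += 1
        assert hits >= 48

    def test_mirror_alignment_under_reverse_complement(self, config, rng):
        genome = simulate_genome(3000, seed=rng)
        rc_genome = GenomeRecord("rc", reverse_complement(genome.seq))
        idx, rc_idx = build_fm_index(genome), build_fm_index(rc_genome)
        for _ in range(10):
            pos = int(rng.integers(0, genome.n - 50))
            read = make_read(genome.seq[pos:pos + 50])
            fwd = align_read(idx, genome, read, config)
            rev = align_read(rc_idx, rc_genome, read, config)
            assert len(fwd) == len(rev) == 1
            assert rev[0].strand == "-"
            assert rev[0].pos == genome.n - (fwd[0].pos + 50)


class TestAlignAll:
    def test_zero_reads(self, small_genome, config):
        recs, stats = align_all([], small_genome, config)
        assert recs == [] and stats.total_reads == 0
        assert stats.fraction_aligned == 0.0

    def test_all_n_reads_unaligned(self, small_genome, config):
        reads = [make_read("N" * 40, rid=f"r{i}") for i in range(3)]
        recs, stats = align_all(reads, small_genome, config)
        assert stats.aligned_reads == 0 and recs == []

    def test_error_free_simulated_reads_all_align(self, config, rng):
        genome = simulate_genome(20000, seed=rng)
        reads = []
        for i in range(300):
            pos = int(rng.integers(0, genome.n - 50))
            seq = genome.seq[pos:pos + 50]
            if rng.random() < 0.5:
                seq = reverse_complement(seq)
            reads.append(make_read(seq, rid=f"r{i}"))
        _, stats = align_all(reads, genome, config)
        assert stats.fraction_aligned == 1.0

    def test_deterministic_output(self, config, rng):
        genome = simulate_genome(5000, seed=rng)
        reads = [make_read(genome.seq[i * 37:i * 37 + 40], rid=f"r{i}")
                 for i in range(60)]
        a1, _ = align_all(reads, genome, config)
        a2, _ = align_all(reads, genome, config)
        assert a1 == a2


class TestSamOutput:
    def test_sam_parses_and_flags_correct(self, tmp_path, config, rng):
        genome = simulate_genome(2000, seed=rng)
        reads = [
            make_read(genome.seq[100:160], rid="mapped_fwd"),
            make_read(reverse_complement(genome.seq[300:360]), rid="mapped_rev"),
            make_read("N" * 60, rid="unmapped"),
        ]
        alns, _ = align_all(reads, genome, config)
        sam = tmp_path / "out.sam"
        write_sam(sam, reads, alns, genome)
        import pysam

        with pysam.AlignmentFile(str(sam), "r") as fh:
            by_name = {r.query_name: r for r in fh}
        assert by_name["mapped_fwd"].reference_start == 100
        assert not by_name["mapped_fwd"].is_reverse
        assert by_name["mapped_rev"].is_reverse
        assert by_name["unmapped"].is_unmapped
        assert by_name["mapped_fwd"].get_tag("NM") == 0
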