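"""k-mer seeding, banded alignment and split-read realignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from indelscout import (
    DiagonalHit,
    ReadGroupStats,
    Scoring,
    banded_align,
    generate_reference,
    kmer_diagonals,
    left_align_indel,
    resolve_breakpoint,
    select_diagonal,
    split_align,
)
from indelscout.splitread import indel_runs_from_ops, revcomp

from oracles import kmer_matches_brute, nw_affine_score

R = ReadGroupStats("rg", 440, 560, "+-", sigma=20.0)

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


class TestKmerDiagonals:
    def test_identity(self):
        s = "ACGTACGTTTGCA"
        hits = kmer_diagonals(s, s, 5)
        counts = {km for i in range(len(s) - 4) for km in [s[i : i + 5]]}
        assert hits[0].diag == 0
        assert hits[0].unique_kmer_count == len(counts)

    def test_internal_deletion_gives_two_diagonals(self, rng):
        read = generate_reference(60, seed=42)
        ref = read[:30] + read[33:]  # 3 bp removed from the middle
        hits = kmer_diagonals(read, ref, 8)
        brute = kmer_matches_brute(read, ref, 8)
        assert {h.diag for h in hits} == set(brute)
        for h in hits:
            assert h.unique_kmer_count == len(brute[h.diag])
        assert {0, -3} <= {h.diag for h in hits}

    def test_homopolymer_has_no_unique_kmers(self):
        assert kmer_diagonals("A" * 40, "A" * 100, 10) == []

    def test_short_read_empty(self):
        assert kmer_diagonals("ACGT", "ACGTACGTACGT", 6) == []

    @given(seed=st.integers(0, 500))
    def test_locality(self, seed):
        """Hits are unchanged by window content outside matched positions."""
        read = generate_reference(40, seed=seed)
        pad1 = generate_reference(50, seed=seed + 1000)
        pad2 = generate_reference(50, seed=seed + 2000)
        h1 = kmer_diagonals(read, pad1 + read + pad1, 11)
        h2 = kmer_diagonals(read, pad2 + read + pad2, 11)
        d1 = {h.diag - 50 for h in h1 if h.anchor_pos >= 50 and h.anchor_pos < 90}
        d2 = {h.diag - 50 for h in h2 if h.anchor_pos >= 50 and h.anchor_pos < 90}
        assert 0 in d1 and 0 in d2


class TestSelectDiagonal:
    def test_dominant_count(self):
        hits = [DiagonalHit(0, 9, 100), DiagonalHit(40, 2, 140)]
        assert select_diagonal(hits, 0).diag == 0

    def test_tie_broken_by_distance_to_anchor(self):
        hits = [DiagonalHit(5, 5, 430), DiagonalHit(80, 5, 800)]
        assert select_diagonal(hits, 400).anchor_pos == 430

    def test_full_tie_takes_leftmost(self):
        hits = [DiagonalHit(10, 5, 500), DiagonalHit(20, 5, 300)]
        assert select_diagonal(hits, 400).anchor_pos == 300

    def test_empty_signals_no_seed(self):
        assert select_diagonal([], 0) is None


class TestBandedAlign:
    def test_identity_score(self):
        s = "ACGTACGTGGCA"
        aln = banded_align(s, s, 0, 3)
        assert aln.score == len(s)
        assert aln.ops == [("=", len(s))]

    def test_single_substitution(self):
        s = "ACGTACGTGGCA"
        t = s[:5] + ("A" if s[5] != "A" else "C") + s[6:]
        aln = banded_align(s, t, 0, 5)
        assert aln.score == (len(s) - 1) * 1 - 2

    def test_gap_cost_model(self):
        # deleting 3 bases costs open + 3*extend = 7
        ref = "ACGTAACCGGTTACGT"
        seq = ref[:8] + ref[11:]
        aln = banded_align(seq, ref, 0, 5)
        assert aln.score == len(seq) * 1 - 4 - 3 * 1
        assert ("D", 3) in aln.ops

    def test_bad_band_raises(self):
        with pytest.raises(ValueError):
            banded_align("ACGT", "ACGT", 0, 0)
        with pytest.raises(ValueError):
            banded_align("ACGTACGT", "AC", 0, 2)  # band cannot reach (n, m)

    @given(st.integers(0, 10_000))
    @settings(max_examples=40)
    def test_full_band_equals_nw_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, m = int(rng.integers(5, 40)), int(rng.integers(5, 40))
        a = "".join(rng.choice(list("ACGT"), n))
        b = "".join(rng.choice(list("ACGT"), m))
        W = n + m
        assert banded_align(a, b, 0, W).score == nw_affine_score(a, b)

    def test_score_recomputable_from_ops(self):
        sc = Scoring()
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = "".join(rng.choice(list("ACGT"), 30))
            b = "".join(rng.choice(list("ACGT"), 33))
            aln = banded_align(a, b, 0, 70)
            total = 0
            for op, ln in aln.ops:
                if op == "=":
                    total += sc.match * ln
                elif op == "X":
                    total += sc.mismatch * ln
                else:
                    total += sc.gap_open + sc.gap_extend * ln
            assert total == aln.score


class TestLeftAlign:
    def test_deletion_in_homopolymer_shifts_left(self):
        ref = "GGGAAAATTT"
        # deleting [5,7) 'AA' is equivalent to deleting [3,5)
        assert left_align_indel(ref, "DEL", 5, 7) == (3, 5, "")

    def test_nonrepetitive_unchanged(self):
        ref = "GACTGTCA"
        assert left_align_indel(ref, "DEL", 3, 5) == (3, 5, "")

    def test_insertion_rotates_through_repeat(self):
        ref = "GGGAAATTT"
        bp, _, seq = left_align_indel(ref, "INS", 6, 6, "AA")
        assert bp == 3 and seq == "AA"

    def test_random_repeats_normalize_to_truth(self, rng):
        """Implanted deletions in repetitive contexts: left-aligning the
        detected right-edge representation recovers the left-aligned truth."""
        for _ in range(100):
            unit = "".join(rng.choice(list("ACGT"), int(rng.integers(1, 4))))
            copies = int(rng.integers(3, 8))
            ref = generate_reference(50, seed=int(rng.integers(1e6))) + unit * copies \
                + generate_reference(50, seed=int(rng.integers(1e6)))
            run_start = 50
            size = len(unit)
            # truth: delete the first unit of the tract
            tl, tr, _ = left_align_indel(ref, "DEL", run_start, run_start + size)
            # detected at the last unit of the tract
            det = run_start + (copies - 1) * size
            dl, dr, _ = left_align_indel(ref, "DEL", det, det + size)
            assert (dl, dr) == (tl, tr)

    def test_resolve_breakpoint_single_run(self):
        ref = "GGGAAAATTT"
        ops = [("=", 5), ("D", 2), ("=", 3)]
        assert resolve_breakpoint(ops, ref, 0) == (3, 5, "")

    def test_resolve_breakpoint_rejects_multiple_runs(self):
        with pytest.raises(ValueError):
            resolve_breakpoint([("=", 3), ("D", 1), ("=", 3), ("I", 2), ("=", 2)],
                               "ACGTACGTACGT", 0, "ACGTAACGTA")

    def test_multi_run_ops_split_into_records(self):
        ref = "ACGTAACCGGTTACGTAACCGGTT"
        ops = [("=", 4), ("D", 2), ("=", 6), ("I", 3), ("=", 8)]
        runs = indel_runs_from_ops(ops, ref, 0, "ACGTCCGGTTTTTACGTAACCG")
        assert [r[0] for r in runs] == ["DEL", "INS"]


class TestSplitAlign:
    def _place(self, ref, read, bp):
        """Helper: mate anchored downstream of the event."""
        return split_align(read, ref, bp + 250, R, chrom="chr1", read_name="q")

    def test_deletion_exact_breakpoints(self):
        ref = generate_reference(2000, seed=1)
        bp = 1000
        size = 25
        mutated = ref[:bp] + ref[bp + size :]
        read = mutated[bp - 60 : bp + 40]  # spans the junction, 60/40 flanks
        ev = self._place(ref, read, bp)
        assert ev is not None
        tl, tr, _ = left_align_indel(ref, "DEL", bp, bp + size)
        assert (ev.kind, ev.bp_left, ev.bp_right) == ("DEL", tl, tr)
        assert ev.left_flank >= 10 and ev.right_flank >= 10

    def test_insertion_sequence_recovered(self):
        ref = generate_reference(2000, seed=2)
        bp = 900
        ins = "ACGTTGCA"
        mutated = ref[:bp] + ins + ref[bp:]
        read = mutated[bp - 50 : bp + len(ins) + 42]
        ev = self._place(ref, read, bp)
        assert ev is not None
        tb, _, tseq = left_align_indel(ref, "INS", bp, bp, ins)
        assert (ev.kind, ev.bp_left, ev.ins_seq) == ("INS", tb, tseq)

    def test_reference_read_yields_none(self):
        ref = generate_reference(2000, seed=3)
        read = ref[1000:1100]
        assert self._place(ref, read, 1050) is None

    def test_never_exceeds_maxsrdelsize(self):
        ref = generate_reference(5000, seed=4)
        bp, size = 2000, 1500
        mutated = ref[:bp] + ref[bp + size :]
        read = mutated[bp - 50 : bp + 50]
        ev = split_align(read, ref, bp + 200, R, maxsrdelsize=1000)
        assert ev is None
        ev2 = split_align(read, ref, bp + 200, R, maxsrdelsize=2000)
        assert ev2 is not None and ev2.size == size

    def test_revcomp_orientation_recovered(self):
        ref = generate_reference(2000, seed=6)
        bp, size = 1000, 20
        mutated = ref[:bp] + ref[bp + size :]
        read = revcomp(mutated[bp - 55 : bp + 45])
        ev = split_align(read, ref, bp - 300, R, try_revcomp=True, chrom="chr1")
        assert ev is not None
        tl, tr, _ = left_align_indel(ref, "DEL", bp, bp + size)
        assert (ev.bp_left, ev.bp_right) == (tl, tr)

    @given(seed=st.integers(0, 300))
    @settings(max_examples=30)
    def test_error_free_reads_match_truth_exactly(self, seed):
        """No phantom events: on error-free reads over one implant, any
        reported evidence equals the left-aligned truth."""
        rng = np.random.default_rng(seed)
        ref = generate_reference(3000, seed=seed + 1)
        bp = 1500
        size = int(rng.integers(1, 50))
        kind = "DEL" if rng.random() < 0.5 else "INS"
        if kind == "DEL":
            mutated = ref[:bp] + ref[bp + size :]
            truth = left_align_indel(ref, "DEL", bp, bp + size)
        else:
            ins = "".join(rng.choice(list("ACGT"), size))
            mutated = ref[:bp] + ins + ref[bp:]
            truth = left_align_indel(ref, "INS", bp, bp, ins)
        offset = int(rng.integers(12, 88))
        read = mutated[bp - offset : bp - offset + 100]
        ev = split_align(read, ref, bp + 200, R, chrom="chr1")
        if ev is not None:
            assert (ev.bp_left, ev.bp_right, ev.ins_seq) == truth
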