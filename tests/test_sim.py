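"""Simulator: reference generation, implantation, read geometry, BAM
signatures, and the reciprocal-overlap evaluator."""

import numpy as np
import pysam
import pytest

from indelscout import (
    IndelCall,
    TruthRecord,
    evaluate_calls,
    generate_reference,
    implant_indels,
    simulate_pairs,
)
from indelscout.sim import CoordMap, apply_truth, emit_truth_bam, invert_truth


class TestGenerateReference:
    def test_deterministic(self):
        assert generate_reference(10000, seed=1) == generate_reference(10000, seed=1)

    def test_seed_changes_sequence(self):
        assert generate_reference(5000, seed=1) != generate_reference(5000, seed=2)

    def test_gc_content_bound(self):
        seq = generate_reference(1_000_000, gc=0.5, seed=4)
        gcfrac = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gcfrac - 0.5) < 0.01

    def test_zero_length_errors(self):
        with pytest.raises(ValueError):
            generate_reference(0)

    def test_repeat_injection(self):
        seq = generate_reference(1000, seed=1, repeats=[(100, "AT", 20)])
        assert seq[100:140] == "AT" * 20


class TestImplantIndels:
    def test_single_deletion_length(self):
        ref = generate_reference(5000, seed=9)
        mut, truth = implant_indels(ref, 1, 0, (10, 10), seed=1)
        assert len(mut) == len(ref) - 10
        assert truth[0].kind == "DEL" and truth[0].size == 10

    def test_round_trip(self):
        ref = generate_reference(60_000, seed=10)
        mut, truth = implant_indels(ref, 20, 20, (1, 80), seed=2)
        assert invert_truth(mut, truth, ref) == ref
        assert apply_truth(ref, truth) == mut

    def test_spacing_invariant(self):
        ref = generate_reference(200_000, seed=11)
        _, truth = implant_indels(ref, 50, 50, (1, 100), seed=3, min_spacing=250)
        truth = sorted(truth, key=lambda t: t.bp_left)
        for a, b in zip(truth, truth[1:]):
            assert b.bp_left - a.bp_right >= 2 * 100  # >= 2 * read_len apart
        # non-overlap
        for a, b in zip(truth, truth[1:]):
            assert a.bp_right <= b.bp_left


class TestSimulatePairs:
    def test_total_bases_near_expectation(self):
        mut = generate_reference(1_000_000, seed=12)
        pairs = simulate_pairs(mut, coverage=20, read_len=100, seed=1)
        total = sum(len(p.seq1) + len(p.seq2) for p in pairs)
        assert abs(total - 2e7) / 2e7 < 0.05

    def test_error_free_reads_match_haplotype(self):
        mut = generate_reference(50_000, seed=13)
        pairs = simulate_pairs(mut, coverage=2, error_rate=0.0, seed=2)
        for p in pairs[:200]:
            assert p.seq1 == mut[p.start : p.start + 100]
            assert p.seq2 == mut[p.start + p.frag - 100 : p.start + p.frag]

    def test_seed_reproducibility(self):
        mut = generate_reference(20_000, seed=14)
        a = simulate_pairs(mut, coverage=2, seed=7)
        b = simulate_pairs(mut, coverage=2, seed=7)
        assert [(p.start, p.frag, p.seq1, p.seq2) for p in a] == [
            (p.start, p.frag, p.seq1, p.seq2) for p in b
        ]


class TestEmitTruthBam:
    def _emit(self, tmp_path, ref, truth, pairs):
        out = str(tmp_path / "t.bam")
        emit_truth_bam(pairs, ref, truth, out)
        return out

    def test_no_implants_all_full_match(self, tmp_path):
        ref = generate_reference(40_000, seed=20)
        pairs = simulate_pairs(ref, coverage=3, error_rate=0.0, seed=3)
        bam_path = self._emit(tmp_path, ref, [], pairs)
        with pysam.AlignmentFile(bam_path) as bam:
            for read in bam.fetch(until_eof=True):
                assert not read.is_unmapped
                assert read.cigarstring == "100M"
                assert read.is_proper_pair

    def test_large_deletion_inflates_outer_distance(self, tmp_path):
        ref = generate_reference(40_000, seed=21)
        truth = [TruthRecord("DEL", "chr1", 20_000, 20_400)]
        mut = apply_truth(ref, truth)
        pairs = simulate_pairs(mut, coverage=10, error_rate=0.0, seed=4)
        bam_path = self._emit(tmp_path, ref, truth, pairs)
        inflated = []
        with pysam.AlignmentFile(bam_path) as bam:
            for read in bam.fetch(until_eof=True):
                if (
                    read.is_read1
                    and not read.is_unmapped
                    and not read.mate_is_unmapped
                    and read.reference_end is not None
                    and read.reference_end <= 20_000
                    and read.next_reference_start >= 20_400
                ):
                    inflated.append(abs(read.template_length))
        assert inflated
        # straddling pairs: outer distance ~ insert + 400
        assert all(750 <= i <= 1150 for i in inflated)
        assert abs(np.mean(inflated) - 900) < 40

    def test_small_deletion_gets_gapped_cigar(self, tmp_path):
        ref = generate_reference(40_000, seed=22)
        truth = [TruthRecord("DEL", "chr1", 20_000, 20_010)]
        mut = apply_truth(ref, truth)
        pairs = simulate_pairs(mut, coverage=15, error_rate=0.0, seed=5)
        bam_path = self._emit(tmp_path, ref, truth, pairs)
        gapped = clipped = 0
        with pysam.AlignmentFile(bam_path) as bam:
            for read in bam.fetch("chr1", 19_900, 20_110):
                cig = read.cigarstring or ""
                if "D" in cig:
                    gapped += 1
                    assert "10D" in cig
                    # spanning reads anchor >= 10 bases on both sides
                    first, last = read.cigartuples[0], read.cigartuples[-1]
                    assert first[0] == 0 and first[1] >= 10
                    assert last[0] == 0 and last[1] >= 10
                elif "S" in cig:
                    clipped += 1
        assert gapped > 0

    def test_insertion_read_inside_is_unmapped(self, tmp_path):
        ref = generate_reference(40_000, seed=23)
        ins = generate_reference(300, seed=24)
        truth = [TruthRecord("INS", "chr1", 20_000, 20_000, ins)]
        mut = apply_truth(ref, truth)
        pairs = simulate_pairs(mut, coverage=15, error_rate=0.0, seed=6)
        bam_path = self._emit(tmp_path, ref, truth, pairs)
        unmapped = 0
        with pysam.AlignmentFile(bam_path) as bam:
            for read in bam.fetch(until_eof=True):
                if read.is_unmapped:
                    unmapped += 1
                    assert not read.mate_is_unmapped
        assert unmapped > 0


def tcall(bp_left, bp_right, kind="DEL", ins=None):
    return IndelCall(kind=kind, chrom="chr1", bp_left=bp_left, bp_right=bp_right,
                     ins_seq=ins, n_sr=1)


def tdel(bp_left, bp_right):
    return TruthRecord("DEL", "chr1", bp_left, bp_right)


class TestEvaluateCalls:
    def test_exact_match_is_tp(self):
        res = evaluate_calls([tcall(100, 200)], [tdel(100, 200)])
        assert (res.tp, res.fp, res.fn) == (1, 0, 0)
        assert res.matches[0][2] is True  # breakpoint-exact

    def test_quarter_overlap_fails_reciprocity(self):
        # overlap 50 < 0.5 * 200 on the truth side
        res = evaluate_calls([tcall(100, 150)], [tdel(100, 300)])
        assert (res.tp, res.fp, res.fn) == (0, 1, 1)

    def test_exactly_half_overlap_validates(self):
        # overlap 100 == 0.5 * truth length and 1.0 * call length
        res = evaluate_calls([tcall(100, 200)], [tdel(100, 300)])
        assert (res.tp, res.fp, res.fn) == (1, 0, 0)
        assert res.matches[0][2] is False

    def test_each_truth_consumes_one_call(self):
        res = evaluate_calls([tcall(100, 200), tcall(100, 200)], [tdel(100, 200)])
        assert (res.tp, res.fp, res.fn) == (1, 1, 0)

    def test_counts_partition(self):
        calls = [tcall(100, 200), tcall(5000, 5050), tcall(9000, 9100)]
        truth = [tdel(100, 200), tdel(7000, 7040)]
        res = evaluate_calls(calls, truth)
        assert res.tp + res.fp == len(calls)
        assert res.tp + res.fn == len(truth)

    def test_insertion_rule_window_and_length(self):
        truth = [TruthRecord("INS", "chr1", 1000, 1000, "ACGTACGT")]
        near = tcall(1010, 1010, kind="INS", ins="ACGTACGT")
        assert evaluate_calls([near], truth).tp == 1
        far = tcall(1200, 1200, kind="INS", ins="ACGTACGT")
        assert evaluate_calls([far], truth).tp == 0
        wrong_len = tcall(1000, 1000, kind="INS", ins="AC")
        assert evaluate_calls([wrong_len], truth).tp == 0

    def test_percentages(self):
        res = evaluate_calls(
            [tcall(100, 200), tcall(500, 560)], [tdel(100, 200), tdel(900, 950)]
        )
        assert res.fp_pct_of_observed == pytest.approx(50.0)
        assert res.fn_pct_of_truth == pytest.approx(50.0)


class TestCoordMap:
    def test_ref_positions_across_events(self):
        truth = [
            TruthRecord("DEL", "chr1", 100, 130),
            TruthRecord("INS", "chr1", 500, 500, "ACGTA"),
        ]
        cmap = CoordMap(1000, truth)
        assert cmap.ref_pos(50) == 50
        assert cmap.ref_pos(100) == 130       # first base after the deletion
        assert cmap.ref_pos(469) == 499       # last collinear base before INS
        assert cmap.ref_pos(472) is None      # inside inserted sequence
        assert cmap.ref_pos(475) == 500       # first base after the insertion
        assert cmap.ref_pos(480) == 505
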