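"""Synthetic data: reference generation, truth-indel implantation,
paired-end read simulation and truth-aware BAM emission, plus the
reciprocal-overlap evaluator.

The generator emulates the signatures a short-read mapper leaves around
implanted homozygous indels on an Illumina-style paired-end library
(orientation '+-', 100 bp reads, insert 500 +/- 30, 20x by default):
gapped CIGARs for reads cleanly spanning a small indel, soft-clips at the
event edge otherwise, unmapped records for reads inside large insertions,
and concordantly oriented pairs with inflated (deleted) or shrunken
(inserted) outer distances across large events.  It does not model
mapper-specific artefacts, quality-score profiles or indel-induced
mismapping; reads are placed where the coordinate map says they belong.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pysam

from .graph import IndelCall

BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class TruthRecord:
    """One implanted indel, on original-reference coordinates (0-based,
    half-open for deletions; insertions have ``bp_left == bp_right``).
    Implants are homozygous, non-overlapping and well separated."""

    kind: str
    chrom: str
    bp_left: int
    bp_right: int
    ins_seq: str = ""
    zygosity: str = "hom"

    @property
    def size(self) -> int:
        return (self.bp_right - self.bp_left) if self.kind == "DEL" else len(self.ins_seq)


def generate_reference(
    length: int,
    gc: float = 0.5,
    seed: int = 0,
    repeats: Optional[Sequence[Tuple[int, str, int]]] = None,
) -> str:
    """Random reference sequence; reproducible for a fixed seed.

    ``repeats`` optionally injects ``(pos, unit, n_copies)`` tandem tracts
    for hard-case tests.
    """
    if length <= 0:
        raise ValueError("reference length must be positive")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = rng.choice(BASES, size=length, p=p)
    if repeats:
        for pos, unit, n in repeats:
            tract = (unit * n)[: max(0, length - pos)]
            seq[pos : pos + len(tract)] = list(tract)
    return "".join(seq)


SizeSampler = Union[Tuple[int, int], Callable[[np.random.Generator], int]]


def _draw_size(sampler: SizeSampler, rng: np.random.Generator) -> int:
    if callable(sampler):
        return int(sampler(rng))
    lo, hi = sampler
    return int(rng.integers(lo, hi + 1))


from .splitread import left_align_indel  # noqa: E402  (cycle-free)


def implant_indels(
    ref: str,
    n_del: int,
    n_ins: int,
    size_sampler: SizeSampler = (1, 50),
    seed: int = 0,
    *,
    chrom: str = "chr1",
    min_spacing: int = 300,
) -> Tuple[str, List[TruthRecord]]:
    """Implant homozygous deletions and insertions into ``ref``.

    Truth records are stored left-aligned so that caller output (also
    left-aligned) can be compared breakpoint-exactly.  Events are kept at
    least ``min_spacing`` bases apart edge-to-edge.
    """
    rng = np.random.default_rng(seed)
    occupied: List[Tuple[int, int]] = []  # sorted (start, end) on ref

    def far_enough(lo: int, hi: int) -> bool:
        idx = bisect.bisect_left(occupied, (lo, hi))
        for j in (idx - 1, idx):
            if 0 <= j < len(occupied):
                s, e = occupied[j]
                if lo - e < min_spacing and s - hi < min_spacing:
                    return False
        return True

    truths: List[TruthRecord] = []
    kinds = ["DEL"] * n_del + ["INS"] * n_ins
    attempts = 0
    max_attempts = 10000 * max(1, len(kinds))
    ki = 0
    while ki < len(kinds):
        if attempts > max_attempts:
            raise RuntimeError("could not place implants with the requested spacing")
        attempts += 1
        kind = kinds[ki]
        size = _draw_size(size_sampler, rng)
        if kind == "DEL":
            if len(ref) < size + 2 * min_spacing:
                raise ValueError("reference too short for requested deletions")
            l = int(rng.integers(min_spacing, len(ref) - size - min_spacing))
            l, r, _ = left_align_indel(ref, "DEL", l, l + size)
            if not far_enough(l, r):
                continue
            bisect.insort(occupied, (l, r))
            truths.append(TruthRecord("DEL", chrom, l, r))
        else:
            p = int(rng.integers(min_spacing, len(ref) - min_spacing))
            ins = "".join(rng.choice(BASES, size=size))
            p, _, ins = left_align_indel(ref, "INS", p, p, ins)
            if not far_enough(p, p):
                continue
            bisect.insort(occupied, (p, p))
            truths.append(TruthRecord("INS", chrom, p, p, ins))
        ki += 1

    truths.sort(key=lambda t: (t.bp_left, t.bp_right))
    mutated = apply_truth(ref, truths)
    return mutated, truths


def apply_truth(ref: str, truths: Sequence[TruthRecord]) -> str:
    """Rebuild the mutated haplotype from the reference and truth list."""
    parts: List[str] = []
    cur = 0
    for t in sorted(truths, key=lambda t: t.bp_left):
        parts.append(ref[cur : t.bp_left])
        if t.kind == "INS":
            parts.append(t.ins_seq)
            cur = t.bp_left
        else:
            cur = t.bp_right
    parts.append(ref[cur:])
    return "".join(parts)


def invert_truth(mutated: str, truths: Sequence[TruthRecord], ref: str) -> str:
    """Undo the implants (requires the original reference for deleted
    sequence); round-trips with :func:`apply_truth`."""
    parts: List[str] = []
    mcur = rcur = 0
    for t in sorted(truths, key=lambda t: t.bp_left):
        seg = t.bp_left - rcur
        parts.append(mutated[mcur : mcur + seg])
        mcur += seg
        if t.kind == "INS":
            mcur += len(t.ins_seq)
            rcur = t.bp_left
        else:
            parts.append(ref[t.bp_left : t.bp_right])
            rcur = t.bp_right
    parts.append(mutated[mcur:])
    return "".join(parts)


class CoordMap:
    """Piecewise map from mutated-haplotype coordinates back to the
    original reference, with the implant junctions made explicit."""

    def __init__(self, ref_len: int, truths: Sequence[TruthRecord]):
        self.blocks: List[Tuple[int, int, int]] = []  # (mut_start, mut_end, ref_start)
        self.events: List[Tuple[str, int, int, int]] = []
        # DEL: ('DEL', mut_pos, ref_l, ref_r); INS: ('INS', mut_start, mut_end, ref_pos)
        mcur = rcur = 0
        for t in sorted(truths, key=lambda t: t.bp_left):
            seg = t.bp_left - rcur
            self.blocks.append((mcur, mcur + seg, rcur))
            mcur += seg
            if t.kind == "DEL":
                self.events.append(("DEL", mcur, t.bp_left, t.bp_right))
                rcur = t.bp_right
            else:
                self.events.append(("INS", mcur, mcur + len(t.ins_seq), t.bp_left))
                mcur += len(t.ins_seq)
                rcur = t.bp_left
        self.blocks.append((mcur, mcur + (ref_len - rcur), rcur))
        self.mut_len = mcur + (ref_len - rcur)
        self._block_starts = [b[0] for b in self.blocks]

    def ref_pos(self, mpos: int) -> Optional[int]:
        """Reference coordinate of mutated position, None inside an insertion."""
        bi = bisect.bisect_right(self._block_starts, mpos) - 1
        ms, me, rs = self.blocks[bi]
        if mpos < me or (mpos == me and bi == len(self.blocks) - 1):
            return rs + (mpos - ms)
        return None  # falls inside an inserted segment

    def events_in(self, s: int, e: int) -> List[Tuple[str, int, int, int]]:
        out = []
        for ev in self.events:
            if ev[0] == "DEL":
                if s < ev[1] < e:
                    out.append(ev)
            else:
                if s < ev[2] and e > ev[1]:
                    out.append(ev)
        return out


@dataclass
class SimPair:
    name: str
    start: int  # fragment start on the mutated haplotype
    frag: int
    seq1: str  # forward-orientation bases actually sequenced (errors applied)
    seq2: str


def simulate_pairs(
    mutated_ref: str,
    coverage: float = 20.0,
    read_len: int = 100,
    insert_mean: float = 500.0,
    insert_sd: float = 30.0,
    error_rate: float = 0.001,
    seed: int = 0,
) -> List[SimPair]:
    """Uniform-start paired-end fragments from the mutated haplotype.

    Fragment lengths are Normal(insert_mean, insert_sd) truncated at
    ``2*read_len``; per-base substitution errors at ``error_rate``;
    orientation '+-'.
    """
    rng = np.random.default_rng(seed)
    n = len(mutated_ref)
    n_pairs = int(round(coverage * n / (2 * read_len)))
    pairs: List[SimPair] = []
    arr = np.frombuffer(mutated_ref.encode(), dtype="S1")
    for idx in range(n_pairs):
        frag = max(2 * read_len, int(round(rng.normal(insert_mean, insert_sd))))
        if frag > n:
            frag = n
        start = int(rng.integers(0, n - frag + 1))
        s1 = mutated_ref[start : start + read_len]
        s2 = mutated_ref[start + frag - read_len : start + frag]
        if error_rate > 0:
            s1 = _apply_errors(s1, error_rate, rng)
            s2 = _apply_errors(s2, error_rate, rng)
        pairs.append(SimPair(f"frag{idx:07d}", start, frag, s1, s2))
    return pairs


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    if hits.size == 0:
        return seq
    chars = list(seq)
    for i in hits:
        alts = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alts[int(rng.integers(0, 3))]
    return "".join(chars)


def _align_interval(
    s: int,
    e: int,
    cmap: CoordMap,
    *,
    min_anchor: int,
    max_gap_del: int,
    max_gap_ins: int,
) -> Optional[Tuple[int, List[Tuple[int, int]]]]:
    """Place a mutated-haplotype interval on the reference.

    Returns (ref_pos, cigartuples) or None for an unmappable read.
    CIGAR op codes are pysam's (0=M, 1=I, 2=D, 4=S).
    """
    events = cmap.events_in(s, e)
    if not events:
        return cmap.ref_pos(s), [(0, e - s)]
    ev = events[0]  # implant spacing guarantees at most one per read
    if ev[0] == "DEL":
        _, mpos, ref_l, ref_r = ev
        left, right = mpos - s, e - mpos
        d = ref_r - ref_l
        if left >= min_anchor and right >= min_anchor and d <= max_gap_del:
            return cmap.ref_pos(s), [(0, left), (2, d), (0, right)]
        if left >= right:
            if left < min_anchor:
                return None
            return cmap.ref_pos(s), [(0, left), (4, right)]
        if right < min_anchor:
            return None
        return ref_r, [(4, left), (0, right)]
    _, bs, be, q = ev
    L = be - bs
    left_ref = max(0, bs - s)
    right_ref = max(0, e - be)
    if left_ref == 0 and right_ref == 0:
        return None  # read lies entirely within the insertion
    if left_ref >= min_anchor and right_ref >= min_anchor and L <= max_gap_ins:
        return q - left_ref, [(0, left_ref), (1, L), (0, right_ref)]
    if left_ref >= right_ref:
        if left_ref < min_anchor:
            return None
        return q - left_ref, [(0, left_ref), (4, (e - s) - left_ref)]
    if right_ref < min_anchor:
        return None
    return q, [(4, (e - s) - right_ref), (0, right_ref)]


def emit_truth_bam(
    pairs: Sequence[SimPair],
    ref: str,
    truths: Sequence[TruthRecord],
    out_bam: str,
    *,
    chrom: str = "chr1",
    read_len: int = 100,
    min_anchor: int = 10,
    max_gap_del: int = 30,
    max_gap_ins: int = 30,
    mq0_frac: float = 0.0,
    seed: int = 0,
    rg_id: str = "sim",
) -> None:
    """Write a coordinate-sorted, indexed BAM with the caller-visible
    alignment signatures implied by the implant coordinate map."""
    cmap = CoordMap(len(ref), truths)
    rng = np.random.default_rng(seed)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": chrom, "LN": len(ref)}],
        "RG": [{"ID": rg_id, "SM": "sample", "PL": "ILLUMINA"}],
    }
    kw = dict(min_anchor=min_anchor, max_gap_del=max_gap_del, max_gap_ins=max_gap_ins)

    records = []
    for pair in pairs:
        s1, e1 = pair.start, pair.start + read_len
        s2, e2 = pair.start + pair.frag - read_len, pair.start + pair.frag
        a1 = _align_interval(s1, e1, cmap, **kw)
        a2 = _align_interval(s2, e2, cmap, **kw)
        if a1 is None and a2 is None:
            continue  # fully unplaceable fragment: dropped (no anchor)
        mq1 = 0 if rng.random() < mq0_frac else 60
        mq2 = 0 if rng.random() < mq0_frac else 60
        records.append((pair, a1, a2, mq1, mq2))

    segs = []
    for pair, a1, a2, mq1, mq2 in records:
        pos1 = a1[0] if a1 else (a2[0] if a2 else 0)
        pos2 = a2[0] if a2 else pos1
        ref_end1 = pos1 + sum(l for op, l in a1[1] if op in (0, 2)) if a1 else pos1
        ref_end2 = pos2 + sum(l for op, l in a2[1] if op in (0, 2)) if a2 else pos2
        if a1 and a2:
            outer = max(ref_end1, ref_end2) - min(pos1, pos2)
            tlen1, tlen2 = (outer, -outer) if pos1 <= pos2 else (-outer, outer)
        else:
            tlen1 = tlen2 = 0

        for which, aln, mq, seq, tlen in (
            ("r1", a1, mq1, pair.seq1, tlen1),
            ("r2", a2, mq2, pair.seq2, tlen2),
        ):
            seg = pysam.AlignedSegment()
            seg.query_name = pair.name
            seg.query_sequence = seq
            seg.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            seg.set_tag("RG", rg_id)
            mate_aln = a2 if which == "r1" else a1
            mate_pos = (mate_aln[0] if mate_aln else (aln[0] if aln else 0))
            flag = 0x1 | (0x40 if which == "r1" else 0x80)
            if which == "r2":
                flag |= 0x10  # reverse strand
                flag |= 0x20 if a1 else 0
            else:
                flag |= 0x20  # mate on reverse strand
            if aln is None:
                flag |= 0x4
                seg.flag = flag | (0x8 if mate_aln is None else 0)
                seg.reference_id = 0
                seg.reference_start = mate_pos
                seg.mapping_quality = 0
                seg.next_reference_id = 0
                seg.next_reference_start = mate_pos
                seg.template_length = 0
            else:
                if mate_aln is None:
                    flag |= 0x8
                else:
                    flag |= 0x2  # both mates placed: call it proper
                seg.flag = flag
                seg.reference_id = 0
                seg.reference_start = aln[0]
                seg.mapping_quality = mq
                seg.cigartuples = aln[1]
                seg.next_reference_id = 0
                seg.next_reference_start = mate_pos
                seg.template_length = tlen
            segs.append(seg)

    segs.sort(key=lambda s: (s.reference_start, s.query_name, s.flag))
    with pysam.AlignmentFile(out_bam, "wb", header=header) as bam:
        for seg in segs:
            bam.write(seg)
    pysam.index(out_bam)


def write_fasta(seq: str, path: str, chrom: str = "chr1", width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")
    pysam.faidx(path)


@dataclass
class SimBundle:
    """Everything one simulation run produced."""

    ref: str
    mutated: str
    truth: List[TruthRecord]
    fasta_path: str
    bam_path: str
    chrom: str = "chr1"


def simulate_dataset(
    out_dir: str,
    seed: int = 0,
    *,
    length: int = 1_000_000,
    n_del: int = 50,
    n_ins: int = 50,
    size_sampler: SizeSampler = (1, 50),
    coverage: float = 20.0,
    read_len: int = 100,
    insert_mean: float = 500.0,
    insert_sd: float = 30.0,
    error_rate: float = 0.001,
    gc: float = 0.5,
    min_spacing: int = 300,
    mq0_frac: float = 0.0,
    chrom: str = "chr1",
    ref: Optional[str] = None,
    truth: Optional[List[TruthRecord]] = None,
    prefix: str = "sim",
) -> SimBundle:
    """One-stop simulation: reference -> implants -> reads -> BAM/FASTA.

    ``ref``/``truth`` may be supplied to resequence an existing genome
    (e.g. the same mutated haplotype for tag-mode sample B).
    """
    import os

    if ref is None:
        ref = generate_reference(length, gc=gc, seed=seed)
    if truth is None:
        mutated, truth = implant_indels(
            ref, n_del, n_ins, size_sampler, seed=seed + 1,
            chrom=chrom, min_spacing=min_spacing,
        )
    else:
        mutated = apply_truth(ref, truth)
    pairs = simulate_pairs(
        mutated, coverage=coverage, read_len=read_len, insert_mean=insert_mean,
        insert_sd=insert_sd, error_rate=error_rate, seed=seed + 2,
    )
    fasta_path = os.path.join(out_dir, f"{prefix}.fa")
    bam_path = os.path.join(out_dir, f"{prefix}.bam")
    write_fasta(ref, fasta_path, chrom=chrom)
    emit_truth_bam(
        pairs, ref, truth, bam_path, chrom=chrom, read_len=read_len,
        mq0_frac=mq0_frac, seed=seed + 3,
    )
    return SimBundle(ref=ref, mutated=mutated, truth=list(truth),
                     fasta_path=fasta_path, bam_path=bam_path, chrom=chrom)


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class EvalResult:
    tp: int
    fp: int
    fn: int
    matches: List[Tuple[object, TruthRecord, bool]]  # (call, truth, breakpoint-exact)
    unmatched_calls: List[object]
    unmatched_truth: List[TruthRecord]

    @property
    def n_calls(self) -> int:
        return self.tp + self.fp

    @property
    def fp_pct_of_observed(self) -> float:
        return 100.0 * self.fp / self.n_calls if self.n_calls else 0.0

    @property
    def fn_pct_of_truth(self) -> float:
        total = self.tp + self.fn
        return 100.0 * self.fn / total if total else 0.0

    @property
    def recall(self) -> float:
        total = self.tp + self.fn
        return self.tp / total if total else 1.0

    def exact_fraction(self) -> float:
        return (
            sum(1 for _, _, exact in self.matches if exact) / len(self.matches)
            if self.matches
            else 1.0
        )


def _call_size(call) -> Optional[int]:
    if call.kind == "DEL":
        return call.bp_right - call.bp_left
    ins = getattr(call, "ins_seq", None)
    if ins:
        return len(ins)
    smin = getattr(call, "size_min", None)
    smax = getattr(call, "size_max", None)
    if smin is not None and smax is not None:
        return (smin + smax) // 2
    return None


def evaluate_calls(
    calls: Sequence[object],
    truth: Sequence[TruthRecord],
    min_reciprocal: float = 0.5,
    *,
    ins_pos_window: int = 30,
    ins_len_tol: float = 0.25,
) -> EvalResult:
    """Match calls against truth records.

    Deletions validate on reciprocal overlap: the shared interval must
    cover at least ``min_reciprocal`` of BOTH the truth and the call.
    Insertions validate on position (within ``ins_pos_window``) and length
    (within ``ins_len_tol`` relative tolerance, skipped for calls without
    a length).  Matching is greedy best-first, one call per truth record.
    """
    candidates: List[Tuple[float, int, int, bool]] = []  # (quality, call_i, truth_i, exact)
    for ci, call in enumerate(calls):
        for ti, t in enumerate(truth):
            if call.kind != t.kind or getattr(call, "chrom", t.chrom) != t.chrom:
                continue
            if t.kind == "DEL":
                ov = min(call.bp_right, t.bp_right) - max(call.bp_left, t.bp_left)
                if ov <= 0:
                    continue
                tlen = t.bp_right - t.bp_left
                clen = call.bp_right - call.bp_left
                if ov < min_reciprocal * tlen or ov < min_reciprocal * clen:
                    continue
                exact = call.bp_left == t.bp_left and call.bp_right == t.bp_right
                quality = ov / max(tlen, clen)
            else:
                dist = abs(call.bp_left - t.bp_left)
                if dist > ins_pos_window:
                    continue
                clen = _call_size(call)
                tlen = t.size
                if clen is not None and abs(clen - tlen) > ins_len_tol * tlen:
                    continue
                ins = getattr(call, "ins_seq", None)
                exact = call.bp_left == t.bp_left and (ins == t.ins_seq or ins is None)
                quality = 1.0 / (1.0 + dist)
            candidates.append((quality, ci, ti, exact))

    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    used_calls: Dict[int, bool] = {}
    used_truth: Dict[int, bool] = {}
    matches: List[Tuple[object, TruthRecord, bool]] = []
    for quality, ci, ti, exact in candidates:
        if ci in used_calls or ti in used_truth:
            continue
        used_calls[ci] = True
        used_truth[ti] = True
        matches.append((calls[ci], truth[ti], exact))

    unmatched_calls = [c for i, c in enumerate(calls) if i not in used_calls]
    unmatched_truth = [t for i, t in enumerate(truth) if i not in used_truth]
    return EvalResult(
        tp=len(matches),
        fp=len(unmatched_calls),
        fn=len(unmatched_truth),
        matches=matches,
        unmatched_calls=unmatched_calls,
        unmatched_truth=unmatched_truth,
    )


def truth_to_calls(truth: Sequence[TruthRecord]) -> List[IndelCall]:
    """Represent truth records as calls (for writing a truth VCF)."""
    out = []
    for t in truth:
        out.append(
            IndelCall(
                kind=t.kind,
                chrom=t.chrom,
                bp_left=t.bp_left,
                bp_right=t.bp_right,
                ins_seq=t.ins_seq if t.kind == "INS" else None,
                n_sr=1,
            )
        )
    return out
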