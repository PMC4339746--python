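"""Split-read realignment: k-mer diagonal seeding plus banded dynamic
programming, yielding base-exact indel breakpoints.

A candidate read (partially aligned, or the unaligned mate of an anchored
read) is realigned in two stages.  Stage one seeds the read against the
reference window ``[mpos - b, mpos + b]`` around the anchor position and
picks the diagonal sharing the most k-mers that are unique within the
read.  Stage two seeds the read segment left unexplained by that diagonal
inside the deletion search window (``maxsrdelsize`` wide) -- or, for
insertions, just around the first diagonal.  The offset between the two
diagonals fixes the indel size exactly; the split point between the two
read halves is then chosen to maximise the number of matching bases, and
the resulting indel is left-aligned (shifted to its smallest reference
coordinate producing the identical alternate haplotype).

Each half is verified with a banded global alignment (affine gap costs,
O(N*W) time / band-limited space) before evidence is emitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .bamio import ReadGroupStats

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# k-mer diagonal seeding


@dataclass(frozen=True)
class DiagonalHit:
    """One candidate diagonal: ``diag = ref_start - read_start``."""

    diag: int
    unique_kmer_count: int
    anchor_pos: int  # leftmost reference coordinate of the seeded band


def _diag_table(read_seq: str, ref_window: str, k: int) -> Dict[int, List[int]]:
    """Map diagonal -> sorted read positions of unique-k-mer matches."""
    n = len(read_seq)
    if n < k or len(ref_window) < k:
        return {}
    counts: Dict[str, int] = {}
    pos_of: Dict[str, int] = {}
    for i in range(n - k + 1):
        km = read_seq[i : i + k]
        counts[km] = counts.get(km, 0) + 1
        pos_of[km] = i
    unique = {km: p for km, p in pos_of.items() if counts[km] == 1}
    table: Dict[int, List[int]] = {}
    for j in range(len(ref_window) - k + 1):
        km = ref_window[j : j + k]
        i = unique.get(km)
        if i is not None:
            table.setdefault(j - i, []).append(i)
    return table


def kmer_diagonals(read_seq: str, ref_window: str, k: int) -> List[DiagonalHit]:
    """Vote for alignment diagonals using k-mers unique within the read.

    Returns hits sorted by descending unique-k-mer count (ties: smaller
    diagonal first).  A read shorter than ``k`` yields an empty list, as
    does a read with no unique k-mers (e.g. a homopolymer).
    """
    if k < 4:
        raise ValueError("k must be >= 4")
    table = _diag_table(read_seq, ref_window, k)
    hits = [
        DiagonalHit(diag=d, unique_kmer_count=len(ps), anchor_pos=d + min(ps))
        for d, ps in table.items()
    ]
    hits.sort(key=lambda h: (-h.unique_kmer_count, h.diag))
    return hits


def select_diagonal(
    hits: Sequence[DiagonalHit], mpos: int, expected_side: Optional[str] = None
) -> Optional[DiagonalHit]:
    """Pick the seeded diagonal: most unique k-mers, then nearest to the
    anchor position ``mpos``, then leftmost.  ``expected_side`` is accepted
    for interface symmetry but the distance criterion already encodes it.

    Returns None on empty ``hits`` (no seed: caller falls through to the
    insertion check or discards the read).
    """
    if not hits:
        return None
    return min(hits, key=lambda h: (-h.unique_kmer_count, abs(h.anchor_pos - mpos), h.anchor_pos))


# ---------------------------------------------------------------------------
# banded global alignment (affine gaps)


@dataclass(frozen=True)
class Scoring:
    """Alignment scores; a gap of length L costs ``gap_open + L*gap_extend``
    (both stored as penalties, i.e. negative)."""

    match: int = 1
    mismatch: int = -2
    gap_open: int = -4
    gap_extend: int = -1


DEFAULT_SCORING = Scoring()

_NEG = float("-inf")


@dataclass
class BandedAlignment:
    read_interval: Tuple[int, int]
    ref_interval: Tuple[int, int]
    score: int
    ops: List[Tuple[str, int]]  # runs of '=', 'X', 'I' (gap in ref), 'D'

    @property
    def matches(self) -> int:
        return sum(ln for op, ln in self.ops if op == "=")

    def identity(self) -> float:
        aligned = sum(ln for op, ln in self.ops if op in "=X")
        return self.matches / aligned if aligned else 0.0


def banded_align(
    seq: str,
    ref_segment: str,
    diag: int = 0,
    W: int = 15,
    scoring: Scoring = DEFAULT_SCORING,
) -> BandedAlignment:
    """Global alignment restricted to the band ``|j - i - diag| <= W``.

    Only O(N*W) cells are evaluated.  Raises ValueError when W < 1 or when
    the band cannot carry a global path from (0,0) to (n,m).
    """
    if W < 1:
        raise ValueError("band width W must be >= 1")
    n, m = len(seq), len(ref_segment)
    lo_d, hi_d = diag - W, diag + W
    if not (lo_d <= 0 <= hi_d and lo_d <= m - n <= hi_d):
        raise ValueError("band does not admit a global alignment path")

    go, ge = scoring.gap_open, scoring.gap_extend
    # three-state DP rows; index j clipped to the band per row
    M = [[_NEG] * (m + 1) for _ in range(n + 1)]
    X = [[_NEG] * (m + 1) for _ in range(n + 1)]  # gap in ref ('I')
    Y = [[_NEG] * (m + 1) for _ in range(n + 1)]  # gap in seq ('D')
    M[0][0] = 0.0
    for j in range(1, min(m, hi_d) + 1):
        Y[0][j] = go + ge * j
    for i in range(1, n + 1):
        if -i >= lo_d:
            X[i][0] = go + ge * i
        jlo = max(1, i + lo_d)
        jhi = min(m, i + hi_d)
        si = seq[i - 1]
        for j in range(jlo, jhi + 1):
            sub = scoring.match if si == ref_segment[j - 1] else scoring.mismatch
            best_prev = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            if best_prev > _NEG:
                M[i][j] = best_prev + sub
            up = max(M[i - 1][j] + go + ge, X[i - 1][j] + ge, Y[i - 1][j] + go + ge)
            if up > _NEG:
                X[i][j] = up
            left = max(M[i][j - 1] + go + ge, Y[i][j - 1] + ge, X[i][j - 1] + go + ge)
            if left > _NEG:
                Y[i][j] = left

    final = max(M[n][m], X[n][m], Y[n][m])
    if final == _NEG:
        raise ValueError("no alignment within band")

    # traceback
    ops_rev: List[str] = []
    i, j = n, m
    state = max(("M", M[n][m]), ("X", X[n][m]), ("Y", Y[n][m]), key=lambda t: t[1])[0]
    while i > 0 or j > 0:
        if state == "M":
            sub = scoring.match if seq[i - 1] == ref_segment[j - 1] else scoring.mismatch
            ops_rev.append("=" if sub == scoring.match else "X")
            target = M[i][j] - sub
            i, j = i - 1, j - 1
            for st, val in (("M", M[i][j]), ("X", X[i][j]), ("Y", Y[i][j])):
                if val == target:
                    state = st
                    break
        elif state == "X":
            ops_rev.append("I")
            target = X[i][j] - ge
            i -= 1
            if X[i][j] == target:
                state = "X"
            elif M[i][j] == target - go:
                state = "M"
            else:
                state = "Y"
        else:
            ops_rev.append("D")
            target = Y[i][j] - ge
            j -= 1
            if Y[i][j] == target:
                state = "Y"
            elif M[i][j] == target - go:
                state = "M"
            else:
                state = "X"

    ops: List[Tuple[str, int]] = []
    for op in reversed(ops_rev):
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + 1)
        else:
            ops.append((op, 1))
    return BandedAlignment(
        read_interval=(0, n), ref_interval=(0, m), score=int(final), ops=ops
    )


# ---------------------------------------------------------------------------
# breakpoint normalisation


def left_align_indel(
    ref: str, kind: str, bp_left: int, bp_right: int, ins_seq: str = ""
) -> Tuple[int, int, str]:
    """Shift an indel to the smallest reference coordinate producing the
    identical alternate haplotype (homopolymer/repeat normalisation)."""
    if kind == "DEL":
        l, r = bp_left, bp_right
        while l > 0 and ref[l - 1] == ref[r - 1]:
            l -= 1
            r -= 1
        return l, r, ""
    p, s = bp_left, ins_seq
    while p > 0 and s and s[-1] == ref[p - 1]:
        s = ref[p - 1] + s[:-1]
        p -= 1
    return p, p, s


def indel_runs_from_ops(
    ops: Sequence[Tuple[str, int]], ref: str, ref_start: int, read_seq: str
) -> List[Tuple[str, int, int, str]]:
    """Extract every indel run from an op list as left-aligned
    ``(kind, bp_left, bp_right, ins_seq)`` tuples.

    Used both to canonicalise split alignments and to harvest gapped
    primary alignments in tag mode (where a CIGAR may carry several runs;
    each is resolved independently).
    """
    out = []
    rpos, qpos = ref_start, 0
    for op, ln in ops:
        if op in "M=X":
            rpos += ln
            qpos += ln
        elif op == "D":
            l, r, _ = left_align_indel(ref, "DEL", rpos, rpos + ln)
            out.append(("DEL", l, r, ""))
            rpos += ln
        elif op == "I":
            p, _, s = left_align_indel(ref, "INS", rpos, rpos, read_seq[qpos : qpos + ln])
            out.append(("INS", p, p, s))
            qpos += ln
        elif op in "SH":
            if op == "S":
                qpos += ln
        else:
            raise ValueError(f"unsupported op {op!r}")
    return out


def resolve_breakpoint(
    ops: Sequence[Tuple[str, int]], ref: str, ref_start: int, read_seq: str = ""
) -> Tuple[int, int, str]:
    """Canonical (left-aligned) breakpoints for an op list containing
    exactly one indel run."""
    runs = indel_runs_from_ops(ops, ref, ref_start, read_seq)
    if len(runs) != 1:
        raise ValueError(f"expected exactly one indel run, found {len(runs)}")
    _, l, r, s = runs[0]
    return l, r, s


# ---------------------------------------------------------------------------
# two-stage split alignment


@dataclass
class SplitReadEvidence:
    """One read split across an indel: exact breakpoints on the reference.

    For a deletion the deleted interval is ``[bp_left, bp_right)``; for an
    insertion ``bp_left == bp_right`` and ``ins_seq`` holds the inserted
    bases.  Flank lengths are the aligned bases on each side of the event.
    """

    kind: str  # 'DEL' | 'INS'
    chrom: str
    bp_left: int
    bp_right: int
    ins_seq: str = ""
    read_name: str = ""
    left_flank: int = 0
    right_flank: int = 0
    mapq_anchor: int = 0
    score: int = 0

    def __post_init__(self) -> None:
        if self.kind == "DEL":
            if self.bp_right <= self.bp_left or self.ins_seq:
                raise ValueError("DEL evidence needs bp_right > bp_left and no ins_seq")
        elif self.kind == "INS":
            if self.bp_right != self.bp_left or not self.ins_seq:
                raise ValueError("INS evidence needs bp_right == bp_left and ins_seq")
        else:
            raise ValueError(f"bad kind {self.kind!r}")
        if self.left_flank < 1 or self.right_flank < 1:
            raise ValueError("both flanks must be >= 1")

    @property
    def size(self) -> int:
        return (self.bp_right - self.bp_left) if self.kind == "DEL" else len(self.ins_seq)

    def key(self) -> Tuple[str, int, int, str]:
        return (self.kind, self.bp_left, self.bp_right, self.ins_seq)


def _diag_match_prefix(seq: str, ref: str, d: int) -> List[int]:
    """Prefix sums of per-position matches of seq on absolute diagonal d."""
    n = len(seq)
    pref = [0] * (n + 1)
    for i in range(n):
        j = i + d
        pref[i + 1] = pref[i] + (1 if 0 <= j < len(ref) and seq[i] == ref[j] else 0)
    return pref


def _verify_half(seq: str, ref: str, d: int, lo: int, hi: int, W: int,
                 min_identity: float, scoring: Scoring) -> Optional[int]:
    """Banded-align read[lo:hi] to its reference segment on diagonal d;
    return the score if identity passes, else None."""
    if hi <= lo:
        return None
    rs, re = lo + d, hi + d
    if rs < 0 or re > len(ref):
        return None
    try:
        aln = banded_align(seq[lo:hi], ref[rs:re], 0, W, scoring)
    except ValueError:
        return None
    if aln.matches < min_identity * (hi - lo):
        return None
    return aln.score


def _split_align_oriented(
    seq: str,
    ref: str,
    mpos: int,
    R: ReadGroupStats,
    maxsrdelsize: int,
    k: int,
    W: int,
    min_flank: int,
    min_identity: float,
    scoring: Scoring,
) -> Optional[Tuple[int, str, int, int, str, int]]:
    """Core of split_align for one read orientation.

    Returns (score, kind, bp_left, bp_right, ins_seq, split_point) or None.
    """
    n = len(seq)
    if n < 2 * min_flank or n < k:
        return None
    w1s = max(0, mpos - R.b)
    w1e = min(len(ref), mpos + R.b + n)
    table1 = _diag_table(seq, ref[w1s:w1e], k)
    hits1 = [
        DiagonalHit(d, len(ps), d + min(ps)) for d, ps in table1.items()
    ]
    hits1.sort(key=lambda h: (-h.unique_kmer_count, h.diag))
    h1 = select_diagonal(hits1, mpos - w1s)
    if h1 is None:
        return None
    d1 = w1s + h1.diag  # absolute: refpos = readpos + d1
    positions = table1[h1.diag]
    rlo, rhi = min(positions), max(positions) + k

    # a read explained end-to-end by one diagonal carries no indel
    full = _diag_match_prefix(seq, ref, d1)
    if full[n] >= min_identity * n:
        return None

    left_tail, right_tail = rlo, n - rhi
    if right_tail >= min_flank and right_tail >= left_tail:
        side = "R"
    elif left_tail >= min_flank:
        side = "L"
    else:
        return None

    if side == "R":
        roff = rhi
        rem = seq[roff:]
        pos = d1 + rhi  # reference coordinate where the anchored prefix ends
        w2s = max(0, pos - n)
        w2e = min(len(ref), pos + maxsrdelsize + n)
    else:
        roff = 0
        rem = seq[:rlo]
        pos = d1 + rlo  # reference coordinate where the anchored suffix starts
        w2s = max(0, pos - maxsrdelsize - n)
        w2e = min(len(ref), pos + 2 * n)
    table2 = _diag_table(rem, ref[w2s:w2e], k)
    hits2 = [DiagonalHit(d, len(ps), d + min(ps)) for d, ps in table2.items()]
    hits2.sort(key=lambda h: (-h.unique_kmer_count, h.diag))
    h2 = select_diagonal(hits2, pos - w2s)
    if h2 is None:
        return None
    d2 = w2s + h2.diag - roff  # absolute diagonal in whole-read coordinates

    dL, dR = (d1, d2) if side == "R" else (d2, d1)
    delta = dR - dL
    if delta == 0:
        return None
    if delta > 0:
        kind, size = "DEL", delta
        if size > maxsrdelsize:
            return None
        ins_len = 0
    else:
        kind, size = "INS", -delta
        ins_len = size
        if ins_len > n - 2 * min_flank:
            return None

    prefL = _diag_match_prefix(seq, ref, dL)
    prefR = _diag_match_prefix(seq, ref, dR)

    best_s, best_sc = None, -1
    hi_s = n - min_flank - ins_len
    for s in range(min_flank, hi_s + 1):
        sc = prefL[s] + (prefR[n] - prefR[s + ins_len])
        if sc > best_sc:
            best_sc, best_s = sc, s
    if best_s is None:
        return None
    s = best_s

    score_l = _verify_half(seq, ref, dL, 0, s, W, min_identity, scoring)
    score_r = _verify_half(seq, ref, dR, s + ins_len, n, W, min_identity, scoring)
    if score_l is None or score_r is None:
        return None

    if kind == "DEL":
        bp_left, bp_right = dL + s, dR + s
        if bp_left < 0 or bp_right > len(ref):
            return None
        ins_seq = ""
    else:
        bp_left = bp_right = dL + s
        if not (0 <= bp_left <= len(ref)):
            return None
        ins_seq = seq[s : s + ins_len]
    return (score_l + score_r, kind, bp_left, bp_right, ins_seq, s)


def split_align(
    read_seq: str,
    ref: str,
    mpos: int,
    R: ReadGroupStats,
    maxsrdelsize: int = 1000,
    k: int = 10,
    W: int = 15,
    *,
    min_flank: int = 10,
    min_identity: float = 0.9,
    scoring: Scoring = DEFAULT_SCORING,
    chrom: str = "",
    read_name: str = "",
    mapq_anchor: int = 0,
    try_revcomp: bool = False,
) -> Optional[SplitReadEvidence]:
    """Realign a candidate read around its anchor and emit indel evidence.

    ``try_revcomp`` additionally tries the reverse complement (needed for
    unaligned mates, whose stored orientation is arbitrary); the
    higher-scoring interpretation wins.  Returns None when no two-part
    alignment supports an indel under the flank/identity acceptance rule.
    """
    candidates = [read_seq]
    if try_revcomp:
        candidates.append(revcomp(read_seq))
    best = None
    for seq in candidates:
        res = _split_align_oriented(
            seq, ref, mpos, R, maxsrdelsize, k, W, min_flank, min_identity, scoring
        )
        if res is not None and (best is None or res[0] > best[0]):
            best = res
    if best is None:
        return None
    score, kind, bp_left, bp_right, ins_seq, s = best
    bp_left, bp_right, ins_seq = left_align_indel(ref, kind, bp_left, bp_right, ins_seq)
    n = len(read_seq)
    right_flank = n - s - (len(ins_seq) if kind == "INS" else 0)
    return SplitReadEvidence(
        kind=kind,
        chrom=chrom,
        bp_left=bp_left,
        bp_right=bp_right,
        ins_seq=ins_seq,
        read_name=read_name,
        left_flank=s,
        right_flank=right_flank,
        mapq_anchor=mapq_anchor,
        score=score,
    )
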