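"""BAM ingestion: insert-size statistics and candidate-read classification.

A paired-end library is summarised per read group by the expected outer
distance (insert size) interval ``[a, b]`` and the expected relative
orientation ``o`` (``'+-'`` for a standard Illumina library).  Fragments
whose alignments depart from that expectation -- a partially aligned mate,
an unaligned mate, or an outer-distance violation -- are the raw material
for split-read and paired-end indel detection, respectively.

Coordinates are 0-based, half-open throughout; conversion to 1-based
happens only when VCF records are written.
"""

from __future__ import annotations

import enum
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np
import pysam

ORIENTATIONS = ("++", "+-", "-+", "--")

#: scale factor turning a median absolute deviation into a normal-consistent
#: standard-deviation estimate
MAD_SCALE = 1.4826

DEFAULT_RG = "default"


class IndelscoutError(RuntimeError):
    """User-facing error (bad input, unusable BAM, missing read group)."""


@dataclass(frozen=True)
class ReadGroupStats:
    """Expected fragment geometry for one read group.

    ``[a, b]`` is the expected outer-distance interval and ``o`` the
    expected relative orientation of the mate that comes earlier on the
    chromosome versus the later one.  ``sigma`` is a robust spread
    estimate of the outer distance (``1.4826 * MAD``) used as a noise
    floor when judging outer-distance violations.
    """

    rg_id: str
    a: int
    b: int
    o: str
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.a <= self.b):
            raise ValueError(f"invalid insert interval [{self.a}, {self.b}]")
        if self.o not in ORIENTATIONS:
            raise ValueError(f"invalid orientation {self.o!r}")


@dataclass
class ReadRecord:
    """Minimal alignment record decoupled from the pysam object.

    ``pos``/``end`` are the 0-based reference start and end of the aligned
    portion (``-1`` when unmapped).  ``cigar`` is a list of
    ``(op_char, length)`` with ops in ``MIDSH=X``.
    """

    name: str
    seq: str
    pos: int = -1
    end: int = -1
    cigar: List[Tuple[str, int]] = field(default_factory=list)
    mapq: int = 0
    is_mapped: bool = False
    is_reverse: bool = False
    is_secondary: bool = False
    chrom: Optional[str] = None

    @classmethod
    def from_pysam(cls, read: "pysam.AlignedSegment") -> "ReadRecord":
        cigar = []
        if read.cigartuples:
            ops = "MIDNSHP=X"
            cigar = [(ops[op], ln) for op, ln in read.cigartuples]
        mapped = not read.is_unmapped
        return cls(
            name=read.query_name,
            seq=read.query_sequence or "",
            pos=read.reference_start if mapped else -1,
            end=read.reference_end if mapped else -1,
            cigar=cigar,
            mapq=read.mapping_quality,
            is_mapped=mapped,
            is_reverse=bool(read.is_reverse),
            is_secondary=bool(read.is_secondary or read.is_supplementary),
            chrom=read.reference_name if mapped else None,
        )

    @property
    def strand(self) -> str:
        return "-" if self.is_reverse else "+"

    def clip_length(self) -> int:
        return sum(ln for op, ln in self.cigar if op in "SH")

    def has_indel(self) -> bool:
        return any(op in "ID" for op, _ in self.cigar)

    def signature_weight(self) -> int:
        """Total clipped + gapped bases; used to pick the read to realign."""
        return sum(ln for op, ln in self.cigar if op in "SHID")


@dataclass
class PairObservation:
    """One sequenced fragment: two mates plus observed geometry.

    ``o`` and ``i`` (observed orientation / outer distance) are defined
    only when both mates aligned to the same reference sequence.
    """

    r1: ReadRecord
    r2: ReadRecord
    rg: ReadGroupStats
    o: Optional[str] = None
    i: Optional[int] = None
    chrom: Optional[str] = None

    def __post_init__(self) -> None:
        if self.r1.name != self.r2.name:
            raise ValueError("mates must share a read name")
        if self.i is not None and self.i < 0:
            raise ValueError("outer distance must be non-negative")

    @classmethod
    def from_reads(cls, r1: ReadRecord, r2: ReadRecord, rg: ReadGroupStats) -> "PairObservation":
        o = i = chrom = None
        if r1.is_mapped and r2.is_mapped and r1.chrom == r2.chrom:
            chrom = r1.chrom
            left, other = (r1, r2) if r1.pos <= r2.pos else (r2, r1)
            o = left.strand + other.strand
            i = max(r1.end, r2.end) - min(r1.pos, r2.pos)
        elif r1.is_mapped:
            chrom = r1.chrom
        elif r2.is_mapped:
            chrom = r2.chrom
        return cls(r1=r1, r2=r2, rg=rg, o=o, i=i, chrom=chrom)

    def read(self, which: str) -> ReadRecord:
        return self.r1 if which == "r1" else self.r2

    def mate_of(self, which: str) -> ReadRecord:
        return self.r2 if which == "r1" else self.r1

    def mpos_for(self, which: str) -> int:
        """Alignment position of the mate anchoring the read ``which``."""
        return self.mate_of(which).pos


class CandidateLabel(enum.Enum):
    SR_PARTIAL = "SR_PARTIAL"
    SR_UNALIGNED_MATE = "SR_UNALIGNED_MATE"
    PE_DISCORDANT = "PE_DISCORDANT"
    NONE = "NONE"


@dataclass(frozen=True)
class CandidateClass:
    label: CandidateLabel
    which_read: Optional[str] = None  # 'r1' | 'r2' | None


def classify_pair(
    P: PairObservation,
    R: ReadGroupStats,
    *,
    call_mode: bool = True,
    min_clip: int = 5,
    margin_sigmas: float = 2.0,
) -> CandidateClass:
    """Assign a fragment to one of the candidate categories.

    * ``SR_PARTIAL`` -- properly paired, but one mate carries a gap or a
      soft-clip of at least ``min_clip`` bases: realign that mate.
    * ``SR_UNALIGNED_MATE`` -- exactly one mate aligned: realign the other.
    * ``PE_DISCORDANT`` -- expected orientation but the outer distance
      falls outside ``[a, b]`` by more than ``margin_sigmas * sigma``
      (noise floor against insert-distribution tails).
    * ``NONE`` -- concordant full-length pair, wrong orientation, or (in
      call mode) a fragment where neither mate maps with MAPQ > 0.
    """
    r1, r2 = P.r1, P.r2
    if not r1.is_mapped and not r2.is_mapped:
        return CandidateClass(CandidateLabel.NONE)

    # fragments with no unambiguous anchor are unusable when calling
    if call_mode and max(
        r1.mapq if r1.is_mapped else 0, r2.mapq if r2.is_mapped else 0
    ) == 0:
        return CandidateClass(CandidateLabel.NONE)

    if r1.is_mapped != r2.is_mapped:
        which = "r1" if not r1.is_mapped else "r2"
        return CandidateClass(CandidateLabel.SR_UNALIGNED_MATE, which)

    if P.o is None or P.o != R.o:
        return CandidateClass(CandidateLabel.NONE)

    assert P.i is not None
    if R.a <= P.i <= R.b:
        w1 = r1.signature_weight() if (r1.has_indel() or r1.clip_length() >= min_clip) else 0
        w2 = r2.signature_weight() if (r2.has_indel() or r2.clip_length() >= min_clip) else 0
        if w1 == w2 == 0:
            return CandidateClass(CandidateLabel.NONE)
        return CandidateClass(CandidateLabel.SR_PARTIAL, "r1" if w1 >= w2 else "r2")

    margin = margin_sigmas * R.sigma
    if P.i > R.b + margin or P.i < R.a - margin:
        return CandidateClass(CandidateLabel.PE_DISCORDANT)
    return CandidateClass(CandidateLabel.NONE)


# ---------------------------------------------------------------------------
# insert-size estimation


def _check_sorted(bam: "pysam.AlignmentFile") -> None:
    hd = bam.header.to_dict().get("HD", {})
    if hd.get("SO") != "coordinate":
        raise IndelscoutError(
            f"{bam.filename.decode() if isinstance(bam.filename, bytes) else bam.filename}: "
            "BAM must be coordinate-sorted (HD:SO=coordinate)"
        )


def _rg_of(read: "pysam.AlignedSegment") -> str:
    try:
        return read.get_tag("RG")
    except KeyError:
        return DEFAULT_RG


def estimate_insert_stats(
    bam_path: str,
    sample_size: int = 10000,
    sd_multiplier: float = 3.0,
) -> Dict[str, ReadGroupStats]:
    """Estimate ``(a, b, o)`` per read group from the first mapped pairs.

    The expected orientation is the modal orientation among sampled pairs;
    the insert interval is ``median +/- sd_multiplier * 1.4826 * MAD`` of
    the sampled outer distances (robust to chimeric outliers), rounded
    outward to integers.  Requires at least 100 usable pairs per group.
    """
    per_rg: Dict[str, List[int]] = defaultdict(list)
    orients: Dict[str, Counter] = defaultdict(Counter)
    collected: Dict[str, int] = defaultdict(int)

    with pysam.AlignmentFile(bam_path, "rb") as bam:
        _check_sorted(bam)
        header_rgs = [rg["ID"] for rg in bam.header.to_dict().get("RG", [])] or [DEFAULT_RG]
        for read in bam.fetch(until_eof=True):
            if (
                read.is_unmapped
                or read.mate_is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or read.is_duplicate
                or read.is_qcfail
                or not read.is_read1
                or read.reference_id != read.next_reference_id
                or read.template_length == 0
            ):
                continue
            rg = _rg_of(read)
            if collected[rg] >= sample_size:
                if all(collected[r] >= sample_size for r in header_rgs):
                    break
                continue
            collected[rg] += 1
            if read.reference_start <= read.next_reference_start:
                o = (("-" if read.is_reverse else "+") + ("-" if read.mate_is_reverse else "+"))
            else:
                o = (("-" if read.mate_is_reverse else "+") + ("-" if read.is_reverse else "+"))
            orients[rg][o] += 1
            per_rg[rg].append(abs(read.template_length))

    stats: Dict[str, ReadGroupStats] = {}
    for rg in header_rgs:
        inserts = per_rg.get(rg, [])
        if len(inserts) < 100:
            raise IndelscoutError(
                f"read group {rg!r}: only {len(inserts)} usable pairs "
                "(need at least 100 to estimate insert statistics)"
            )
        o = orients[rg].most_common(1)[0][0]
        arr = np.asarray(inserts, dtype=float)
        med = float(np.median(arr))
        mad = float(np.median(np.abs(arr - med)))
        sigma = MAD_SCALE * mad
        a = max(1, math.floor(med - sd_multiplier * sigma))
        b = math.ceil(med + sd_multiplier * sigma)
        stats[rg] = ReadGroupStats(rg_id=rg, a=a, b=b, o=o, sigma=sigma)
    return stats


# ---------------------------------------------------------------------------
# candidate streaming


def stream_candidates(
    bam_path: str,
    stats: Dict[str, ReadGroupStats],
    region: Optional[Tuple[str, int, int]] = None,
    *,
    call_mode: bool = True,
    min_clip: int = 5,
    margin_sigmas: float = 2.0,
) -> Iterator[Tuple[CandidateClass, PairObservation]]:
    """Yield classified candidate fragments in reference-coordinate order.

    Mate pairing is resolved internally (each fragment yielded at most
    once); duplicate-flagged, QC-fail and secondary/supplementary records
    are skipped.  A read group absent from ``stats`` is a hard error.
    """
    pending: Dict[str, Tuple["pysam.AlignedSegment", str]] = {}
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        _check_sorted(bam)
        if region is not None:
            it = bam.fetch(region[0], region[1], region[2])
        else:
            it = bam.fetch(until_eof=True)
        for read in it:
            if read.is_secondary or read.is_supplementary or read.is_duplicate or read.is_qcfail:
                continue
            rg = _rg_of(read)
            if rg not in stats:
                raise IndelscoutError(f"read group {rg!r} missing from insert statistics")
            key = read.query_name
            if key not in pending:
                pending[key] = (read, rg)
                continue
            first, _ = pending.pop(key)
            a, b = (first, read) if first.is_read1 else (read, first)
            pair = PairObservation.from_reads(
                ReadRecord.from_pysam(a), ReadRecord.from_pysam(b), stats[rg]
            )
            cls = classify_pair(
                pair, stats[rg], call_mode=call_mode, min_clip=min_clip,
                margin_sigmas=margin_sigmas,
            )
            if cls.label is not CandidateLabel.NONE:
                yield cls, pair
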