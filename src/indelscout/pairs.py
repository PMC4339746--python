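"""Paired-end evidence: insert-size-violating pairs as interval-bounded
indel observations.

A pair aligned with the expected orientation but an outer distance ``i``
outside the read group's ``[a, b]`` implies a deletion (``i > b``, implied
size in ``[i - b, i - a]``) or an insertion (``i < a``, size in
``[a - i, b - i]``) somewhere between the inner alignment ends of the two
mates.  Paired-end evidence bounds the breakpoints to intervals; it never
resolves them to the base.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

from .bamio import PairObservation, ReadGroupStats


@dataclass
class PairedEndEvidence:
    """One discordant pair.  ``region_left``/``region_right`` are the
    reference intervals admitting the left/right breakpoint; for an
    insertion both collapse to the inner span between the mates."""

    kind: str  # 'DEL' | 'INS'
    chrom: str
    region_left: Tuple[int, int]
    region_right: Tuple[int, int]
    size_min: int
    size_max: int
    read_name: str
    i: int
    rg: ReadGroupStats
    flank_lengths: Tuple[int, int] = (0, 0)  # aligned length of each mate

    def __post_init__(self) -> None:
        if self.kind not in ("DEL", "INS"):
            raise ValueError(f"bad kind {self.kind!r}")
        if self.size_min <= 0 or self.size_max < self.size_min:
            raise ValueError("size bounds must satisfy 0 < size_min <= size_max")

    @property
    def inner_left(self) -> int:
        return self.region_left[0]

    @property
    def inner_right(self) -> int:
        return self.region_right[1]


def pair_evidence(
    P: PairObservation,
    R: ReadGroupStats,
    maxpedelsize: int = 100000,
    *,
    margin_sigmas: float = 2.0,
) -> Optional[PairedEndEvidence]:
    """Convert a discordant pair into paired-end evidence, or None.

    Deletions require ``i`` to exceed ``b`` by at least
    ``margin_sigmas * sigma`` (tail-noise floor) and an implied size no
    larger than ``maxpedelsize``.  Insertion evidence (``i < a``) is
    emitted symmetrically but is only size-bounded; whether it survives to
    a call is decided downstream.
    """
    if not (P.r1.is_mapped and P.r2.is_mapped) or P.o != R.o or P.i is None:
        return None
    i = P.i
    left, right = (P.r1, P.r2) if P.r1.pos <= P.r2.pos else (P.r2, P.r1)
    inner_left = left.end
    inner_right = max(right.pos, inner_left)
    margin = margin_sigmas * R.sigma
    flanks = (left.end - left.pos, right.end - right.pos)

    if i > R.b:
        if i - R.b < margin:
            return None
        size_min = i - R.b
        size_max = i - R.a
        if size_min > maxpedelsize:
            return None
        size_max = min(size_max, maxpedelsize, max(size_min, inner_right - inner_left))
        return PairedEndEvidence(
            kind="DEL",
            chrom=P.chrom or "",
            region_left=(inner_left, max(inner_left, inner_right - size_min)),
            region_right=(inner_left + size_min, inner_right),
            size_min=size_min,
            size_max=size_max,
            read_name=P.r1.name,
            i=i,
            rg=R,
            flank_lengths=flanks,
        )
    if i < R.a:
        if R.a - i < margin:
            return None
        return PairedEndEvidence(
            kind="INS",
            chrom=P.chrom or "",
            region_left=(inner_left, inner_right),
            region_right=(inner_left, inner_right),
            size_min=R.a - i,
            size_max=R.b - i,
            read_name=P.r1.name,
            i=i,
            rg=R,
            flank_lengths=flanks,
        )
    return None
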