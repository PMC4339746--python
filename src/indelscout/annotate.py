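"""Call annotation and filtering.

Each call is annotated with alignment statistics over the breakpoint
region: mean depth of coverage, root-mean-square mapping quality, the
number of MAPQ-0 reads, and per-supporting-read flank lengths.  Filters
then keep calls by support count, depth window, RMS mapping quality and
MAPQ-0 fraction, recording the failed threshold for every rejection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pysam

from .graph import IndelCall
from .splitread import SplitReadEvidence


@dataclass
class Annotations:
    avg_depth: float
    rms_mapq: float
    mq0_count: int
    n_overlap: int
    flank_lengths: List[Tuple[int, int]] = field(default_factory=list)


def _region(call: IndelCall) -> Tuple[int, int]:
    # deletions: the deleted interval padded by one base so that reads
    # clipped exactly at a breakpoint still count as "across" it (a
    # homozygous deletion has no reads strictly inside); insertions: the
    # two bases straddling the insertion point
    if call.kind == "DEL":
        return max(0, call.bp_left - 1), call.bp_right + 1
    return max(0, call.bp_left - 1), call.bp_left + 1


def annotate(call: IndelCall, bam: "pysam.AlignmentFile") -> Annotations:
    """Compute alignment statistics across the call's breakpoint region.

    Read-only and deterministic; duplicate/QC-fail/secondary records are
    excluded, matching call mode.
    """
    ref_len = bam.get_reference_length(call.chrom)
    if call.bp_left < 0 or call.bp_right > ref_len:
        raise ValueError(
            f"region {call.chrom}:{call.bp_left}-{call.bp_right} outside reference bounds"
        )
    start, end = _region(call)
    end = min(end, ref_len)

    cov = bam.count_coverage(call.chrom, start, end, quality_threshold=0)
    avg_depth = float(np.sum(cov) / (end - start)) if end > start else 0.0

    mapqs: List[int] = []
    mq0 = 0
    for read in bam.fetch(call.chrom, start, end):
        if (
            read.is_unmapped
            or read.is_secondary
            or read.is_supplementary
            or read.is_duplicate
            or read.is_qcfail
        ):
            continue
        mapqs.append(read.mapping_quality)
        if read.mapping_quality == 0:
            mq0 += 1
    rms = math.sqrt(sum(q * q for q in mapqs) / len(mapqs)) if mapqs else 0.0

    flanks: List[Tuple[int, int]] = []
    for ev in call.evidence:
        if isinstance(ev, SplitReadEvidence):
            flanks.append((ev.left_flank, ev.right_flank))
        else:
            # paired-end evidence: the aligned length of each mate
            flanks.append(ev.flank_lengths)
    return Annotations(
        avg_depth=avg_depth,
        rms_mapq=rms,
        mq0_count=mq0,
        n_overlap=len(mapqs),
        flank_lengths=flanks,
    )


@dataclass(frozen=True)
class FilterThresholds:
    """Defaults: at least two supporting observations, RMS MAPQ >= 10,
    at most half the overlapping reads at MAPQ 0; depth bounds off."""

    min_support: int = 2
    min_rms_mapq: float = 10.0
    max_mq0_frac: float = 0.5
    min_depth: Optional[float] = None
    max_depth: Optional[float] = None


def apply_filters(
    calls: Sequence[IndelCall], thresholds: FilterThresholds = FilterThresholds()
) -> Tuple[List[IndelCall], List[Tuple[IndelCall, str]]]:
    """Partition calls into (kept, rejected-with-reason).

    Order-independent and idempotent: each call is judged on its own
    annotations only.  Calls must be annotated first.
    """
    kept: List[IndelCall] = []
    rejected: List[Tuple[IndelCall, str]] = []
    for call in calls:
        ann: Annotations = call.annotations  # type: ignore[assignment]
        if ann is None:
            raise ValueError("apply_filters requires annotated calls")
        if call.support < thresholds.min_support:
            rejected.append((call, "min_support"))
            continue
        if thresholds.min_depth is not None and ann.avg_depth < thresholds.min_depth:
            rejected.append((call, "min_depth"))
            continue
        if thresholds.max_depth is not None and ann.avg_depth > thresholds.max_depth:
            rejected.append((call, "max_depth"))
            continue
        if ann.rms_mapq < thresholds.min_rms_mapq:
            rejected.append((call, "min_rms_mapq"))
            continue
        if ann.n_overlap and ann.mq0_count / ann.n_overlap > thresholds.max_mq0_frac:
            rejected.append((call, "max_mq0_frac"))
            continue
        kept.append(call)
    return kept, rejected
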