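"""Presence/absence tagging of a call set in a second sample.

Given calls from sample A (e.g. tumor) and a BAM for sample B (e.g.
matched normal), scan B maximally permissively -- including MAPQ-0 reads,
secondary/supplementary records and duplicates -- for any read-level
evidence reproducing each A call: a gapped alignment with the identical
left-aligned indel, a split-realignment of a clipped or unaligned read
yielding the same breakpoints, or a discordant pair whose outer-distance
constraints admit the call.  One supporting read suffices for "present".

Tagging never alters A's calls; output cardinality equals input
cardinality, and adding reads to B can only flip absent -> present.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import pysam

from .bamio import ReadGroupStats
from .graph import IndelCall
from .splitread import indel_runs_from_ops, split_align

_CIGAR_OPS = "MIDNSHP=X"


@dataclass
class TagResult:
    call: IndelCall
    present: bool
    support: int
    missing_contig: bool = False


def _cigar_chars(read: "pysam.AlignedSegment"):
    return [(_CIGAR_OPS[op], ln) for op, ln in (read.cigartuples or [])]


def _matches_call(kind: str, l: int, r: int, ins: str, call: IndelCall) -> bool:
    if kind != call.kind or l != call.bp_left or r != call.bp_right:
        return False
    if kind == "INS" and call.ins_seq is not None:
        return len(ins) == len(call.ins_seq)
    return True


def _sr_evidence_matches(ev, call: IndelCall) -> bool:
    return _matches_call(ev.kind, ev.bp_left, ev.bp_right, ev.ins_seq, call)


def tag_variants(
    calls_A: Sequence[IndelCall],
    bam_B_path: str,
    stats_B: Dict[str, ReadGroupStats],
    ref_fasta: str,
    window: Optional[int] = None,
    *,
    min_clip: int = 5,
    maxsrdelsize: int = 1000,
    k: int = 10,
    W: int = 15,
    margin_sigmas: float = 2.0,
) -> List[TagResult]:
    """Tag every A call with its presence in sample B.

    ``window`` defaults to the largest ``b`` among B's read groups, since
    paired-end evidence can sit a full insert away from the breakpoints.
    """
    default_R = max(stats_B.values(), key=lambda r: r.b)
    w = window if window is not None else default_R.b
    results: List[TagResult] = []
    ref_cache: Dict[str, str] = {}

    with pysam.AlignmentFile(bam_B_path, "rb") as bam, pysam.FastaFile(ref_fasta) as fa:
        refs = set(bam.references)
        for call in calls_A:
            if call.chrom not in refs:
                results.append(TagResult(call, False, 0, missing_contig=True))
                continue
            if call.chrom not in ref_cache:
                ref_cache[call.chrom] = fa.fetch(call.chrom).upper()
            ref = ref_cache[call.chrom]
            start = max(0, call.bp_left - w)
            end = min(len(ref), call.bp_right + w)
            size = call.size or 0
            support = set()
            for read in bam.fetch(call.chrom, start, end):
                if read.is_qcfail:
                    continue
                name = read.query_name
                if name in support:
                    continue
                cig = _cigar_chars(read)

                # (i) gapped alignment reproducing the same indel
                if not read.is_unmapped and any(op in "ID" for op, _ in cig):
                    runs = indel_runs_from_ops(
                        cig, ref, read.reference_start, read.query_sequence or ""
                    )
                    if any(_matches_call(kd, l, r, s, call) for kd, l, r, s in runs):
                        support.add(name)
                        continue

                # (ii) split-realignment of clipped / unaligned reads
                clipped = sum(ln for op, ln in cig if op in "SH") >= min_clip
                unaligned = read.is_unmapped and not read.mate_is_unmapped
                if (clipped or unaligned) and read.query_sequence:
                    R = stats_B.get(read.get_tag("RG") if read.has_tag("RG") else "", default_R)
                    mpos = read.next_reference_start if unaligned else read.reference_start
                    if mpos is not None and mpos >= 0:
                        ev = split_align(
                            read.query_sequence.upper(), ref, mpos, R,
                            maxsrdelsize, k, W, chrom=call.chrom,
                            try_revcomp=unaligned,
                        )
                        if ev is not None and _sr_evidence_matches(ev, call):
                            support.add(name)
                            continue

                # (iii) discordant pair whose constraints admit the call:
                # leftmost mate only (counts each pair once), outside the
                # insert-noise floor, and with the call inside the pair's
                # unsequenced inner span
                if (
                    not read.is_unmapped
                    and not read.mate_is_unmapped
                    and read.reference_id == read.next_reference_id
                    and read.template_length > 0
                ):
                    R = stats_B.get(read.get_tag("RG") if read.has_tag("RG") else "", default_R)
                    i = read.template_length
                    margin = margin_sigmas * R.sigma
                    inner_l = read.reference_end
                    inner_r = read.next_reference_start
                    if (
                        call.kind == "DEL"
                        and i > R.b + margin
                        and (i - R.b) <= size <= (i - R.a)
                        and inner_l <= call.bp_left
                        and call.bp_right <= inner_r
                    ):
                        support.add(name)
                        continue
                    if (
                        call.kind == "INS"
                        and i < R.a - margin
                        and size
                        and (R.a - i) <= size <= (R.b - i)
                        and inner_l <= call.bp_left <= inner_r
                    ):
                        support.add(name)
                        continue
            results.append(TagResult(call, len(support) >= 1, len(support)))
    return results


def annotate_tags(results: Sequence[TagResult]) -> List[IndelCall]:
    """Return the A calls with PRESENT_IN_B / B_SUPPORT INFO keys set."""
    out = []
    for res in results:
        call = res.call
        call.info = dict(call.info)
        call.info["PRESENT_IN_B"] = "yes" if res.present else "no"
        call.info["B_SUPPORT"] = res.support
        out.append(call)
    return out
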