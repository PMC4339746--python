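"""End-to-end call-mode orchestration.

estimate insert stats -> stream candidates -> split-read realignment /
paired-end evidence -> evidence graph -> components -> clique
breakpoints -> SR/PE merge -> annotation -> filters.  Deterministic for
fixed inputs and options: there is no randomised step in call mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import pysam

from .annotate import FilterThresholds, annotate, apply_filters
from .bamio import (
    CandidateLabel,
    ReadGroupStats,
    estimate_insert_stats,
    stream_candidates,
)
from .graph import IndelCall, calls_from_evidence, merge_sr_pe
from .pairs import pair_evidence
from .splitread import Scoring, split_align

log = logging.getLogger("indelscout")


@dataclass
class CallOptions:
    sample_size: int = 10000
    sd_multiplier: float = 3.0
    min_clip: int = 5
    margin_sigmas: float = 2.0
    maxsrdelsize: int = 1000
    maxpedelsize: int = 100000
    kmer_size: int = 10
    band_width: int = 15
    min_flank: int = 10
    min_identity: float = 0.9
    scoring: Scoring = field(default_factory=Scoring)
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    region: Optional[Tuple[str, int, int]] = None
    insert_override: Optional[Tuple[int, int, str]] = None  # (a, b, o) for all groups


@dataclass
class CallResult:
    kept: List[IndelCall]
    rejected: List[Tuple[IndelCall, str]]
    stats: Dict[str, ReadGroupStats]
    stage_counts: Dict[str, int]


def call_indels(
    bam_path: str,
    fasta_path: str,
    options: CallOptions = CallOptions(),
    stats: Optional[Dict[str, ReadGroupStats]] = None,
) -> CallResult:
    """Run the full calling pipeline on one BAM."""
    opt = options
    if stats is None:
        stats = estimate_insert_stats(bam_path, opt.sample_size, opt.sd_multiplier)
    if opt.insert_override is not None:
        a, b, o = opt.insert_override
        stats = {
            rg: ReadGroupStats(rg_id=rg, a=a, b=b, o=o, sigma=s.sigma)
            for rg, s in stats.items()
        }
    for rg, s in stats.items():
        log.info("read group %s: a=%d b=%d o=%s sigma=%.1f", rg, s.a, s.b, s.o, s.sigma)

    counts = {"candidates": 0, "sr_evidence": 0, "pe_evidence": 0}
    per_chrom: Dict[str, list] = {}

    with pysam.FastaFile(fasta_path) as fa:
        ref_cache: Dict[str, str] = {}

        def ref_of(chrom: str) -> str:
            if chrom not in ref_cache:
                ref_cache[chrom] = fa.fetch(chrom).upper()
            return ref_cache[chrom]

        for cls, pair in stream_candidates(
            bam_path, stats, opt.region,
            min_clip=opt.min_clip, margin_sigmas=opt.margin_sigmas,
        ):
            counts["candidates"] += 1
            chrom = pair.chrom
            if chrom is None:
                continue
            ref = ref_of(chrom)
            evs = per_chrom.setdefault(chrom, [])

            if cls.label is CandidateLabel.PE_DISCORDANT:
                pe = pair_evidence(
                    pair, pair.rg, opt.maxpedelsize, margin_sigmas=opt.margin_sigmas
                )
                if pe is not None:
                    counts["pe_evidence"] += 1
                    evs.append(pe)
                # clipped mates of discordant pairs carry the breakpoint:
                # realign them anchored on their own position (the
                # mate-centred window cannot reach across a large event)
                for which in ("r1", "r2"):
                    read = pair.read(which)
                    if not read.is_mapped or read.clip_length() < opt.min_clip:
                        continue
                    ev = split_align(
                        read.seq.upper(), ref, read.pos, pair.rg,
                        opt.maxsrdelsize, opt.kmer_size, opt.band_width,
                        min_flank=opt.min_flank, min_identity=opt.min_identity,
                        scoring=opt.scoring, chrom=chrom, read_name=read.name,
                        mapq_anchor=pair.mate_of(which).mapq,
                    )
                    if ev is not None:
                        counts["sr_evidence"] += 1
                        evs.append(ev)
                continue

            which = cls.which_read or "r1"
            read = pair.read(which)
            anchor = pair.mate_of(which)
            mpos = anchor.pos if anchor.is_mapped else read.pos
            if mpos is None or mpos < 0:
                continue
            ev = split_align(
                read.seq.upper(), ref, mpos, pair.rg,
                opt.maxsrdelsize, opt.kmer_size, opt.band_width,
                min_flank=opt.min_flank, min_identity=opt.min_identity,
                scoring=opt.scoring, chrom=chrom, read_name=read.name,
                mapq_anchor=anchor.mapq if anchor.is_mapped else read.mapq,
                try_revcomp=(cls.label is CandidateLabel.SR_UNALIGNED_MATE),
            )
            if ev is not None:
                counts["sr_evidence"] += 1
                evs.append(ev)

        calls: List[IndelCall] = []
        components = 0
        for chrom in sorted(per_chrom):
            chrom_calls = calls_from_evidence(per_chrom[chrom], chrom)
            components += len(chrom_calls)
            chrom_calls = merge_sr_pe(chrom_calls)
            # paired-end-only insertion evidence is size-ambiguous; keep it
            # only when the implied size clears the insert-noise floor
            pruned = []
            for c in chrom_calls:
                if c.kind == "INS" and c.n_sr == 0:
                    sigma = c.evidence[0].rg.sigma if c.evidence else 0.0
                    if c.size_min is None or c.size_min < 2 * sigma:
                        continue
                pruned.append(c)
            calls.extend(pruned)
        counts["components"] = components
        counts["calls"] = len(calls)

        with pysam.AlignmentFile(bam_path, "rb") as bam:
            for call in calls:
                call.annotations = annotate(call, bam)
        kept, rejected = apply_filters(calls, opt.thresholds)
        counts["kept"] = len(kept)

    log.info(
        "candidates=%d sr=%d pe=%d components=%d calls=%d kept=%d",
        counts["candidates"], counts["sr_evidence"], counts["pe_evidence"],
        counts["components"], counts["calls"], counts["kept"],
    )
    return CallResult(kept=kept, rejected=rejected, stats=stats, stage_counts=counts)
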