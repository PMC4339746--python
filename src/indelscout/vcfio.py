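"""VCF 4.2 emission and parsing for indel calls.

Records are written by hand so that repeated runs are byte-identical;
parsing goes through pysam.  Deletions shorter than the symbolic cutoff
are written with explicit REF/ALT sequences (POS anchored on the base
before the event); longer ones use ``<DEL>`` with END.  Internal 0-based
half-open coordinates are converted to 1-based only here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import pysam

from .annotate import Annotations
from .graph import IndelCall

SYMBOLIC_CUTOFF = 1000

_INFO_LINES = [
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Variant type (DEL or INS)">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="1-based end of the deleted interval">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Signed event length">',
    '##INFO=<ID=NSR,Number=1,Type=Integer,Description="Supporting split reads">',
    '##INFO=<ID=NPE,Number=1,Type=Integer,Description="Supporting discordant pairs">',
    '##INFO=<ID=AVGDP,Number=1,Type=Float,Description="Mean depth across the breakpoint region">',
    '##INFO=<ID=RMSMQ,Number=1,Type=Float,Description="RMS mapping quality across the breakpoint region">',
    '##INFO=<ID=MQ0,Number=1,Type=Integer,Description="MAPQ-0 reads across the breakpoint region">',
    '##INFO=<ID=CIPOS,Number=2,Type=Integer,Description="Confidence interval around POS">',
    '##INFO=<ID=CIEND,Number=2,Type=Integer,Description="Confidence interval around END">',
    '##INFO=<ID=PRESENT_IN_B,Number=1,Type=String,Description="Presence of the variant in sample B (tag mode)">',
    '##INFO=<ID=B_SUPPORT,Number=1,Type=Integer,Description="Supporting reads found in sample B (tag mode)">',
    '##ALT=<ID=DEL,Description="Deletion">',
    '##ALT=<ID=INS,Description="Insertion of unresolved sequence">',
]


def _fetch(fasta: "pysam.FastaFile", chrom: str, start: int, end: int) -> str:
    return fasta.fetch(chrom, max(0, start), end).upper()


def _record(call: IndelCall, fasta: "pysam.FastaFile") -> str:
    chrom = call.chrom
    info: Dict[str, str] = {}
    size = call.size or 0

    if call.kind == "DEL":
        info["SVTYPE"] = "DEL"
        info["END"] = str(call.bp_right)  # 1-based inclusive == 0-based half-open end
        info["SVLEN"] = str(-size)
        if size > SYMBOLIC_CUTOFF:
            pos1 = max(1, call.bp_left)
            ref = _fetch(fasta, chrom, pos1 - 1, pos1)
            alt = "<DEL>"
        elif call.bp_left == 0:
            # event at the contig start: anchor on the following base
            pos1 = 1
            ref = _fetch(fasta, chrom, 0, call.bp_right + 1)
            alt = ref[-1]
        else:
            pos1 = call.bp_left  # anchor base is 0-based bp_left-1
            ref = _fetch(fasta, chrom, pos1 - 1, call.bp_right)
            alt = ref[0]
    else:
        info["SVTYPE"] = "INS"
        info["END"] = str(max(1, call.bp_left))
        if call.ins_seq:
            info["SVLEN"] = str(len(call.ins_seq))
            pos1 = max(1, call.bp_left)
            ref = _fetch(fasta, chrom, pos1 - 1, pos1)
            alt = ref + call.ins_seq if call.bp_left > 0 else call.ins_seq + ref
        else:
            info["SVLEN"] = str(size)
            pos1 = max(1, call.bp_left)
            ref = _fetch(fasta, chrom, pos1 - 1, pos1)
            alt = "<INS>"

    info["NSR"] = str(call.n_sr)
    info["NPE"] = str(call.n_pe)
    ann: Optional[Annotations] = call.annotations  # type: ignore[assignment]
    if ann is not None:
        info["AVGDP"] = f"{ann.avg_depth:.2f}"
        info["RMSMQ"] = f"{ann.rms_mapq:.2f}"
        info["MQ0"] = str(ann.mq0_count)
    if call.ci_left != (0, 0):
        info["CIPOS"] = f"{call.ci_left[0]},{call.ci_left[1]}"
    if call.ci_right != (0, 0):
        info["CIEND"] = f"{call.ci_right[0]},{call.ci_right[1]}"
    for key, val in call.info.items():
        info[str(key)] = str(val)

    info_str = ";".join(f"{k}={v}" for k, v in info.items())
    return "\t".join(
        [chrom, str(pos1), ".", ref, alt, ".", "PASS", info_str]
    )


def write_vcf(
    calls: Sequence[IndelCall], fasta_path: str, out_path: str, source: str = "indelscout"
) -> None:
    """Write calls as VCF 4.2.  Records are sorted internally; the header
    declares every INFO key and all reference contigs."""
    with pysam.FastaFile(fasta_path) as fasta:
        order = {name: i for i, name in enumerate(fasta.references)}
        records = sorted(
            calls, key=lambda c: (order.get(c.chrom, len(order)), c.bp_left, c.bp_right)
        )
        lines = ["##fileformat=VCFv4.2", f"##source={source}"]
        for name, ln in zip(fasta.references, fasta.lengths):
            lines.append(f"##contig=<ID={name},length={ln}>")
        lines.extend(_INFO_LINES)
        lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
        for call in records:
            lines.append(_record(call, fasta))
    with open(out_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_calls_vcf(path: str) -> List[IndelCall]:
    """Parse a VCF written by this package (or any indel VCF with
    SVTYPE/END) back into calls."""
    calls: List[IndelCall] = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            info = dict(rec.info)
            svtype = info.get("SVTYPE")
            ref = rec.ref or ""
            alt = rec.alts[0] if rec.alts else ""
            symbolic = alt.startswith("<")
            if svtype is None:
                svtype = "DEL" if len(ref) > len(alt) else "INS"
            if svtype == "DEL":
                ins_seq = None
                if symbolic:
                    bp_left = rec.start + 1
                    # pysam surfaces the END INFO key as rec.stop
                    bp_right = int(rec.stop)
                elif rec.start == 0 and len(ref) > 1 and alt == ref[-1] and alt != ref[0]:
                    # contig-start convention: anchor follows the event
                    bp_left = 0
                    bp_right = len(ref) - 1
                else:
                    bp_left = rec.start + 1
                    bp_right = rec.start + len(ref)
            else:
                if symbolic or len(alt) <= len(ref):
                    bp_left = bp_right = rec.start + 1
                    ins_seq = None
                elif rec.start == 0 and not alt[: len(ref)] == ref:
                    bp_left = bp_right = 0
                    ins_seq = alt[: len(alt) - len(ref)]
                else:
                    bp_left = bp_right = rec.start + 1
                    ins_seq = alt[len(ref):]
            ci = tuple(info.get("CIPOS", (0, 0)))
            cie = tuple(info.get("CIEND", (0, 0)))
            n_sr = int(info.get("NSR", 0))
            n_pe = int(info.get("NPE", 0))
            if n_sr + n_pe == 0:
                n_sr = 1
            svlen = info.get("SVLEN")
            size = abs(int(svlen)) if svlen is not None else None
            call = IndelCall(
                kind=svtype,
                chrom=rec.chrom,
                bp_left=bp_left,
                bp_right=bp_right,
                ci_left=ci if n_sr == 0 else (0, 0),
                ci_right=cie if n_sr == 0 else (0, 0),
                ins_seq=ins_seq,
                n_sr=n_sr,
                n_pe=n_pe,
                size_min=size,
                size_max=size,
            )
            extra = {}
            for key in ("PRESENT_IN_B", "B_SUPPORT"):
                if key in info:
                    extra[key] = info[key]
            call.info = extra
            calls.append(call)
    return calls
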