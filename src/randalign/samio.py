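"""SAM text emission (primary alignments only).

Coordinates become 1-based here and nowhere else.  Unmapped reads keep their
sequence and quality.  NM (edit distance) and AS (alignment score) tags are
written for aligned records.
"""

from __future__ import annotations

from .alignment import AlignmentResult, InsertSizeModel
from .index import StrobeIndex
from .nucleo import revcomp
from .seeding import REVERSE

__all__ = ["sam_header", "sam_single", "sam_pair"]

FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_READ1 = 0x40
FLAG_READ2 = 0x80


def sam_header(index: StrobeIndex, command_line: str, version: str) -> str:
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for name, length in zip(index.ref_names, index.ref_lengths):
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    lines.append(f"@PG\tID:randalign\tPN:randalign\tVN:{version}\tCL:{command_line}")
    return "\n".join(lines) + "\n"


def _seq_qual(res: AlignmentResult, seq: str, qual: str) -> tuple[str, str]:
    if res.is_aligned and res.strand == REVERSE:
        return revcomp(seq), qual[::-1]
    return seq, qual


def _record(
    name: str,
    flag: int,
    res: AlignmentResult,
    index: StrobeIndex,
    seq: str,
    qual: str,
    rnext: str = "*",
    pnext: int = 0,
    tlen: int = 0,
) -> str:
    if res.is_aligned:
        rname = index.ref_names[res.r_id]
        pos = res.ref_start + 1
        fields = [
            name, str(flag), rname, str(pos), str(res.mapq), res.cigar,
            rnext, str(pnext), str(tlen),
        ]
        fields += list(_seq_qual(res, seq, qual))
        fields += [f"NM:i:{res.edit_distance}", f"AS:i:{res.score}"]
    else:
        fields = [name, str(flag), "*", "0", "0", "*", rnext, str(pnext), "0", seq, qual]
    return "\t".join(fields)


def sam_single(name: str, res: AlignmentResult, index: StrobeIndex, seq: str, qual: str) -> str:
    flag = 0
    if not res.is_aligned:
        flag |= FLAG_UNMAPPED
    elif res.strand == REVERSE:
        flag |= FLAG_REVERSE
    return _record(name, flag, res, index, seq, qual)


def _is_proper(r1: AlignmentResult, r2: AlignmentResult, model: InsertSizeModel) -> bool:
    if not (r1.is_aligned and r2.is_aligned):
        return False
    if r1.r_id != r2.r_id or r1.strand == r2.strand:
        return False
    fwd, rev = (r1, r2) if r1.strand != REVERSE else (r2, r1)
    if fwd.ref_start > rev.ref_end:
        return False
    return rev.ref_end - fwd.ref_start < model.proper_max


def sam_pair(
    name: str,
    res1: AlignmentResult,
    res2: AlignmentResult,
    index: StrobeIndex,
    seq1: str,
    qual1: str,
    seq2: str,
    qual2: str,
    model: InsertSizeModel,
) -> tuple[str, str]:
    """SAM records for a read pair, with mate fields, proper-pair flag, and
    signed TLEN (positive on the leftmost mate)."""
    proper = _is_proper(res1, res2, model)
    tlen1 = tlen2 = 0
    if res1.is_aligned and res2.is_aligned and res1.r_id == res2.r_id:
        left = min(res1.ref_start, res2.ref_start)
        right = max(res1.ref_end, res2.ref_end)
        span = right - left
        if res1.ref_start < res2.ref_start or (
            res1.ref_start == res2.ref_start and res1.ref_end <= res2.ref_end
        ):
            tlen1, tlen2 = span, -span
        else:
            tlen1, tlen2 = -span, span

    def flags(own: AlignmentResult, mate: AlignmentResult, first: bool) -> int:
        fl = FLAG_PAIRED | (FLAG_READ1 if first else FLAG_READ2)
        if proper:
            fl |= FLAG_PROPER
        if not own.is_aligned:
            fl |= FLAG_UNMAPPED
        elif own.strand == REVERSE:
            fl |= FLAG_REVERSE
        if not mate.is_aligned:
            fl |= FLAG_MATE_UNMAPPED
        elif mate.strand == REVERSE:
            fl |= FLAG_MATE_REVERSE
        return fl

    def mate_fields(own: AlignmentResult, mate: AlignmentResult) -> tuple[str, int]:
        if not mate.is_aligned:
            return ("=", own.ref_start + 1) if own.is_aligned else ("*", 0)
        rnext = index.ref_names[mate.r_id]
        if own.is_aligned and own.r_id == mate.r_id:
            rnext = "="
        return rnext, mate.ref_start + 1

    rn1, pn1 = mate_fields(res1, res2)
    rn2, pn2 = mate_fields(res2, res1)
    line1 = _record(name, flags(res1, res2, True), res1, index, seq1, qual1, rn1, pn1, tlen1)
    line2 = _record(name, flags(res2, res1, False), res2, index, seq2, qual2, rn2, pn2, tlen2)
    return line1, line2
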