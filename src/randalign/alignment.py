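"""Base-level extension and single/paired-end alignment.

Candidate regions from the mapping stage are extended into alignments.  When
a merged match spans the same number of bases on read and reference, a
Hamming comparison of the projected read suffices (and is upgraded to a full
Smith-Waterman call if the mismatch count exceeds 5% of the read, since
offsetting indels can fake equal spans).  Unequal spans go straight to
Smith-Waterman.  Scoring is match +1, mismatch -4, gap open -6, gap extend
-1, with a gap of length l costing 6 + (l-1).

Paired-end mode scores candidate pairs jointly: a proper pair (same
reference, forward/reverse orientation, fragment length < mu + 10*sigma under
the insert-size model) earns the log normal density of its fragment length on
top of the two Smith-Waterman scores, while individually placed mates pay a
flat -10 (more than four standard deviations of insert-size penalty).  A mate
with no candidates of its own is rescued by aligning it inside a window of
mu + 5*sigma downstream of its placed partner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .index import StrobeIndex
from .mapping import MapParams, MergedMatch, candidate_regions, mapq
from .nucleo import revcomp
from .seeding import FORWARD, REVERSE

__all__ = [
    "ScoringParams",
    "AlignmentResult",
    "InsertSizeModel",
    "PairScore",
    "extract_segment",
    "smith_waterman",
    "extend_candidate",
    "align_single",
    "estimate_insert_size",
    "score_pair",
    "mate_rescue",
    "align_paired",
    "cigar_read_len",
    "cigar_ref_len",
]

SEGMENT_PAD = 20  # bp margin around the projected read to absorb indels


@dataclass(frozen=True)
class ScoringParams:
    match: int = 1
    mismatch: int = 4
    gap_open: int = 6
    gap_extend: int = 1

    def aligner(self) -> Align.PairwiseAligner:
        return Align.PairwiseAligner(
            mode="local",
            match_score=self.match,
            mismatch_score=-self.mismatch,
            open_gap_score=-self.gap_open,
            extend_gap_score=-self.gap_extend,
        )


@dataclass
class AlignmentResult:
    is_aligned: bool = False
    r_id: int = -1
    ref_start: int = 0
    strand: int = FORWARD
    cigar: str = "*"
    score: int = 0
    edit_distance: int = 0
    mapq: int = 0
    rescued: bool = False

    @property
    def ref_end(self) -> int:
        return self.ref_start + cigar_ref_len(self.cigar)


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    if cigar == "*":
        return []
    ops, num = [], ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.append((ch, int(num)))
            num = ""
    return ops


def cigar_read_len(cigar: str) -> int:
    return sum(n for op, n in parse_cigar(cigar) if op in "MIS=X")


def cigar_ref_len(cigar: str) -> int:
    return sum(n for op, n in parse_cigar(cigar) if op in "MD=XN")


def _compact(ops: list[tuple[str, int]]) -> str:
    out: list[tuple[str, int]] = []
    for op, n in ops:
        if n == 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + n)
        else:
            out.append((op, n))
    return "".join(f"{n}{op}" for op, n in out) or "*"


def extract_segment(
    mm: MergedMatch, read_len: int, ref_seq: str, pad: int = SEGMENT_PAD
) -> tuple[str, int] | None:
    """Reference segment expected to contain the read: the merged-match span
    extended by the read overhangs on both sides plus a small indel pad,
    clipped to the reference.  Returns (segment, start) or None when empty."""
    # q coordinates are already on the orientation-matched read
    start = max(0, mm.r_s - mm.q_s - pad)
    end = min(len(ref_seq), mm.r_e + (read_len - mm.q_e) + pad)
    if end <= start:
        return None
    return ref_seq[start:end], start


def smith_waterman(
    query: str, target: str, scoring: ScoringParams = ScoringParams()
) -> tuple[int, str, int, int]:
    """Local affine-gap alignment of query against target.

    Returns (score, cigar with soft clips covering the whole query,
    target start of the aligned region, edit distance over the aligned
    region).  Returns an unaligned sentinel when no positive-scoring local
    alignment exists."""
    if not query or not target:
        return 0, "*", 0, 0
    aln = scoring.aligner().align(target, query)
    if len(aln) == 0 or aln[0].score <= 0:
        return 0, "*", 0, 0
    best = aln[0]
    tblocks, qblocks = best.aligned
    ops: list[tuple[str, int]] = [("S", int(qblocks[0][0]))]
    nm = 0
    for bi, ((ts, te), (qs, qe)) in enumerate(zip(tblocks, qblocks)):
        if bi > 0:
            dq = qs - qblocks[bi - 1][1]
            dt = ts - tblocks[bi - 1][1]
            if dq:
                ops.append(("I", int(dq)))
                nm += dq
            if dt:
                ops.append(("D", int(dt)))
                nm += dt
        ops.append(("M", int(te - ts)))
        nm += sum(a != b for a, b in zip(target[ts:te], query[qs:qe]))
    ops.append(("S", len(query) - int(qblocks[-1][1])))
    return int(best.score), _compact(ops), int(tblocks[0][0]), int(nm)


def _hamming(read: str, ref_window: str, scoring: ScoringParams) -> tuple[int, int]:
    a = np.frombuffer(read.encode(), np.uint8)
    b = np.frombuffer(ref_window.encode(), np.uint8)
    mism = int((a != b).sum())
    return (len(read) - mism) * scoring.match - mism * scoring.mismatch, mism


def extend_candidate(
    read: str,
    ref_seq: str,
    mm: MergedMatch,
    scoring: ScoringParams = ScoringParams(),
) -> AlignmentResult:
    """Extend one candidate region to a base-level alignment.

    Equal merged-match spans on read and reference dispatch to a Hamming
    comparison of the projected read (upgraded to Smith-Waterman when the
    Hamming distance exceeds 0.05 * read length); unequal spans go straight
    to Smith-Waterman.  Reverse-orientation candidates align the
    reverse-complemented read; all reported coordinates are on the reference
    forward strand."""
    L = len(read)
    oriented = read if mm.o == FORWARD else revcomp(read)
    result = AlignmentResult(strand=mm.o, r_id=mm.r_id)
    best: tuple[int, str, int, int] | None = None  # score, cigar, ref_start, nm
    if mm.a == mm.b:
        proj = mm.r_s - mm.q_s
        if 0 <= proj and proj + L <= len(ref_seq):
            score, mism = _hamming(oriented, ref_seq[proj : proj + L], scoring)
            best = (score, f"{L}M", proj, mism)
            if mism <= 0.05 * L:
                if score <= 0:
                    return result
                result.is_aligned = True
                result.ref_start, result.cigar = proj, best[1]
                result.score, result.edit_distance = score, mism
                return result
    seg = extract_segment(mm, L, ref_seq)
    if seg is not None:
        segment, seg_start = seg
        score, cigar, t_beg, nm = smith_waterman(oriented, segment, scoring)
        if cigar != "*" and (best is None or score > best[0]):
            best = (score, cigar, seg_start + t_beg, nm)
    if best is None or best[0] <= 0:
        return result
    result.is_aligned = True
    result.score, result.cigar, result.ref_start, result.edit_distance = (
        best[0], best[1], best[2], best[3],
    )
    return result


def _extend_ranked(
    read: str,
    index: StrobeIndex,
    cands: list[MergedMatch],
    params: MapParams,
    scoring: ScoringParams,
) -> AlignmentResult | None:
    """Extend candidates in score order with the top-k cap, the drop-off
    threshold, and the perfect-match / edit-distance-1 early stops."""
    if not cands:
        return None
    s1 = cands[0].score
    best: AlignmentResult | None = None
    for mm in cands[: params.max_candidates]:
        if s1 > 0 and mm.score < params.dropoff * s1:
            break
        res = extend_candidate(read, index.ref_seqs[mm.r_id], mm, scoring)
        if res.is_aligned and (best is None or res.score > best.score):
            best = res
        if res.is_aligned and res.edit_distance <= 1:
            # edit distance 0: report immediately; edit distance 1: any
            # further base-level call cannot do better than distance 1
            break
    return best


def align_single(
    read: str,
    index: StrobeIndex,
    params: MapParams = MapParams(),
    scoring: ScoringParams = ScoringParams(),
) -> AlignmentResult:
    """Single-end alignment: candidates ranked by merged-match score, at most
    ``max_candidates`` extended (drop-off 0.5), best Smith-Waterman score
    wins; MAPQ derives from the top two merged-match scores."""
    cands, _ = candidate_regions(read, index, params)
    best = _extend_ranked(read, index, cands, params, scoring)
    if best is None:
        return AlignmentResult()
    s1 = cands[0].score
    s2 = cands[1].score if len(cands) > 1 else 0
    best.mapq = mapq(s1, max(s2, 0), cands[0].n)
    return best


# ---------------------------------------------------------------------------
# paired-end machinery

@dataclass
class InsertSizeModel:
    """Frozen normal model of the outer fragment (template) length."""

    mu: float = 300.0
    sigma: float = 100.0
    n_observations: int = 0

    def log_density(self, d: float) -> float:
        return (
            -0.5 * ((d - self.mu) / self.sigma) ** 2
            - math.log(self.sigma * math.sqrt(2 * math.pi))
        )

    @property
    def proper_max(self) -> float:
        return self.mu + 10 * self.sigma


DEFAULT_INSERT = InsertSizeModel()
SIGMA_FLOOR = 1.0
INDIVIDUAL_PENALTY = 10.0
MATE_RESCUE_MIN_SCORE_FRAC = 0.5


def estimate_insert_size(
    fragment_lengths: list[float], min_obs: int = 100, max_obs: int = 500
) -> InsertSizeModel:
    """Moment estimates of (mu, sigma) from high-confidence fragment
    lengths; observations outside median +/- 10*MAD are discarded first.
    Falls back to the documented defaults below ``min_obs`` observations."""
    obs = np.asarray(fragment_lengths[:max_obs], dtype=float)
    if obs.size >= min_obs:
        med = np.median(obs)
        mad = np.median(np.abs(obs - med))
        keep = obs[np.abs(obs - med) <= 10 * max(mad, 1.0)]
        if keep.size >= min_obs:
            return InsertSizeModel(
                mu=float(keep.mean()),
                sigma=float(max(keep.std(), SIGMA_FLOOR)),
                n_observations=int(keep.size),
            )
    return InsertSizeModel(n_observations=0)


@dataclass(frozen=True)
class PairScore:
    c: int
    proper: bool
    d: float = 0.0


def _pair_geometry(mm1: MergedMatch, mm2: MergedMatch) -> tuple[bool, float]:
    """FR-orientation check and outer fragment span for two merged matches."""
    if mm1.r_id != mm2.r_id or mm1.o == mm2.o:
        return False, 0.0
    fwd, rev = (mm1, mm2) if mm1.o == FORWARD else (mm2, mm1)
    if fwd.r_s > rev.r_e:
        return False, 0.0
    return True, float(rev.r_e - fwd.r_s)


def score_pair(
    mm1: MergedMatch | None, mm2: MergedMatch | None, model: InsertSizeModel
) -> PairScore:
    """Joint map-location count: C_ij = n_i + n_j for proper pairs (same
    reference, FR orientation, fragment < mu + 10*sigma), else the individual
    count of whichever mate is present."""
    if mm1 is not None and mm2 is not None:
        fr, d = _pair_geometry(mm1, mm2)
        if fr and d < model.proper_max:
            return PairScore(mm1.n + mm2.n, True, d)
        return PairScore(max(mm1.n, mm2.n), False)
    single = mm1 or mm2
    return PairScore(single.n if single else 0, False)


def pair_alignment_score(
    sw1: float, sw2: float, model: InsertSizeModel, d: float | None
) -> float:
    """S_ij = SW_i + SW_j + log N(d; mu, sigma) for proper pairs, and
    SW_i + SW_j - 10 for individually placed mates."""
    if d is None:
        return sw1 + sw2 - INDIVIDUAL_PENALTY
    return sw1 + sw2 + model.log_density(d)


def mate_rescue(
    placed: AlignmentResult,
    mate_read: str,
    model: InsertSizeModel,
    index: StrobeIndex,
    scoring: ScoringParams = ScoringParams(),
) -> AlignmentResult:
    """Align a candidate-less mate inside the window [0, mu + 5*sigma]
    nucleotides away from its placed partner, in the expected (opposite)
    orientation.  Accepted only above a score floor of half the read
    length."""
    ref = index.ref_seqs[placed.r_id]
    span = int(model.mu + 5 * model.sigma) + len(mate_read)
    if placed.strand == FORWARD:
        w_s, w_e = placed.ref_start, min(len(ref), placed.ref_start + span)
        oriented = revcomp(mate_read)
        strand = REVERSE
    else:
        w_s, w_e = max(0, placed.ref_end - span), placed.ref_end
        oriented = mate_read
        strand = FORWARD
    if w_e <= w_s:
        return AlignmentResult()
    score, cigar, t_beg, nm = smith_waterman(oriented, ref[w_s:w_e], scoring)
    if cigar == "*" or score < MATE_RESCUE_MIN_SCORE_FRAC * len(mate_read):
        return AlignmentResult()
    return AlignmentResult(
        is_aligned=True, r_id=placed.r_id, ref_start=w_s + t_beg, strand=strand,
        cigar=cigar, score=score, edit_distance=nm, mapq=placed.mapq, rescued=True,
    )


def _oriented(read: str, mm: MergedMatch) -> str:
    return read if mm.o == FORWARD else revcomp(read)


def align_paired(
    read1: str,
    read2: str,
    index: StrobeIndex,
    model: InsertSizeModel = DEFAULT_INSERT,
    params: MapParams = MapParams(),
    scoring: ScoringParams = ScoringParams(),
) -> tuple[AlignmentResult, AlignmentResult]:
    """Paired-end alignment with joint insert-size scoring.

    Candidate locations for the two mates are combined into proper-pair and
    individual configurations, ranked by joint seed count C, extended in rank
    order, and the configuration with the best S_ij wins.  Both mates receive
    the joint MAPQ from the top two S_ij.  A mate without candidates is mate-
    rescued near its placed partner."""
    cands1, _ = candidate_regions(read1, index, params)
    cands2, _ = candidate_regions(read2, index, params)
    if not cands1 and not cands2:
        return AlignmentResult(), AlignmentResult()
    if not cands1 or not cands2:
        read_p, cands_p = (read1, cands1) if cands1 else (read2, cands2)
        read_u = read2 if cands1 else read1
        placed = _extend_ranked(read_p, index, cands_p, params, scoring)
        if placed is None:
            return AlignmentResult(), AlignmentResult()
        s1 = cands_p[0].score
        s2 = cands_p[1].score if len(cands_p) > 1 else 0
        placed.mapq = mapq(s1, max(s2, 0), cands_p[0].n)
        rescued = mate_rescue(placed, read_u, model, index, scoring)
        return (placed, rescued) if cands1 else (rescued, placed)

    top1 = cands1[: params.max_candidates]
    top2 = cands2[: params.max_candidates]
    configs: list[tuple[int, int, int | None, int | None, float | None]] = []
    for i, mm1 in enumerate(top1):
        for j, mm2 in enumerate(top2):
            ps = score_pair(mm1, mm2, model)
            if ps.proper:
                configs.append((ps.c, 0, i, j, ps.d))
    for i, mm1 in enumerate(top1):
        configs.append((mm1.n, 1, i, None, None))
    for j, mm2 in enumerate(top2):
        configs.append((mm2.n, 1, None, j, None))
    configs.sort(key=lambda t: (-t[0], t[1], t[2] if t[2] is not None else 1 << 30,
                                t[3] if t[3] is not None else 1 << 30))

    ext_cache: dict[tuple[int, int], AlignmentResult] = {}

    def extend(mate: int, idx: int) -> AlignmentResult:
        key = (mate, idx)
        if key not in ext_cache:
            read, mm = (read1, top1[idx]) if mate == 1 else (read2, top2[idx])
            ext_cache[key] = extend_candidate(read, index.ref_seqs[mm.r_id], mm, scoring)
        return ext_cache[key]

    best_ind1 = _extend_ranked(read1, index, cands1, params, scoring)
    best_ind2 = _extend_ranked(read2, index, cands2, params, scoring)

    scored: list[tuple[float, int, AlignmentResult | None, AlignmentResult | None, int]] = []
    for rank, (c, _kind, i, j, d) in enumerate(configs[: params.max_candidates]):
        if i is not None and j is not None:
            a1, a2 = extend(1, i), extend(2, j)
            if not (a1.is_aligned and a2.is_aligned):
                continue
            # recompute the fragment span from the base-level alignments
            fwd, rev = (a1, a2) if a1.strand == FORWARD else (a2, a1)
            d_aln = float(rev.ref_end - fwd.ref_start)
            proper = (
                a1.r_id == a2.r_id and a1.strand != a2.strand
                and fwd.ref_start <= rev.ref_end and d_aln < model.proper_max
            )
            s = pair_alignment_score(a1.score, a2.score, model, d_aln if proper else None)
            scored.append((s, c, a1, a2, rank))
        elif i is not None:
            a1 = extend(1, i)
            if a1.is_aligned and best_ind2 is not None:
                s = pair_alignment_score(a1.score, best_ind2.score, model, None)
                scored.append((s, c, a1, best_ind2, rank))
            elif a1.is_aligned:
                scored.append((a1.score - INDIVIDUAL_PENALTY, c, a1, None, rank))
        else:
            a2 = extend(2, j)
            if a2.is_aligned and best_ind1 is not None:
                s = pair_alignment_score(best_ind1.score, a2.score, model, None)
                scored.append((s, c, best_ind1, a2, rank))
            elif a2.is_aligned:
                scored.append((a2.score - INDIVIDUAL_PENALTY, c, None, a2, rank))
    if not scored:
        return AlignmentResult(), AlignmentResult()
    scored.sort(key=lambda t: (-t[0], t[4]))
    # the runner-up for MAPQ must be a *different* placement of the pair:
    # collapse configurations that place both mates identically
    def signature(a1: AlignmentResult | None, a2: AlignmentResult | None):
        def one(a):
            return (a.r_id, a.ref_start, a.strand) if a is not None and a.is_aligned else None
        return one(a1), one(a2)

    seen_sigs: set = set()
    distinct: list[float] = []
    for s, _c, a1c, a2c, _r in scored:
        sig = signature(a1c, a2c)
        if sig not in seen_sigs:
            seen_sigs.add(sig)
            distinct.append(s)
    s1p = distinct[0]
    s2p = distinct[1] if len(distinct) > 1 else None
    best_c = scored[0][1]
    # MAPQ needs positive scores on a ratio scale; shift so the runner-up
    # maps to its relative distance from the top (single candidate: S2 = 0)
    joint_mq = mapq(s1p, max(s2p, 0.0) if s2p is not None else 0.0, best_c)
    a1, a2 = scored[0][2], scored[0][3]
    out1 = a1 if a1 is not None else AlignmentResult()
    out2 = a2 if a2 is not None else AlignmentResult()
    for r in (out1, out2):
        if r.is_aligned:
            r.mapq = joint_mq
    if out1.is_aligned and not out2.is_aligned:
        resc = mate_rescue(out1, read2, model, index, scoring)
        if resc.is_aligned:
            out2 = resc
    elif out2.is_aligned and not out1.is_aligned:
        resc = mate_rescue(out2, read1, model, index, scoring)
        if resc.is_aligned:
            out1 = resc
    return out1, out2
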