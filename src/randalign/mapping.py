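"""Candidate mapping sites: seed lookup, the streaming lowest-d match
filter, merged-match construction, merged-match scoring, and MAPQ.

A *match* is a seed hash shared between read and reference, with coordinates
(r_id, r_s, r_e, q_s, q_e, o).  d is the difference between the seed's span
on the reference and on the read; because seeds are fuzzy, low d indicates a
consistent placement.  Matches are merged into candidate regions when they
overlap on both query and reference with a consistent ordering of the four
strobes; the merged-match score S_M = (min{a, b} - |a - b|) * n rewards long,
span-consistent, seed-dense regions, and MAPQ is derived from the top two
scores, minimap2-style.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .index import LookupStatus, StrobeIndex
from .seeding import Seed, read_seeds

__all__ = [
    "Match",
    "MergedMatch",
    "MapParams",
    "find_matches",
    "merge_matches",
    "score_merged",
    "mapq",
    "rescue_candidates",
    "candidate_regions",
    "map_extension_free",
    "MappingRecord",
]


@dataclass(frozen=True, order=True)
class Match:
    r_id: int
    r_s: int
    r_e: int
    q_s: int
    q_e: int
    o: int

    @property
    def d(self) -> int:
        return abs((self.r_e - self.r_s) - (self.q_e - self.q_s))


@dataclass
class MergedMatch:
    """A maximal group of overlapping, order-consistent matches; the unit of
    candidate mapping locations."""

    r_id: int
    o: int
    q_s: int
    q_e: int
    r_s: int
    r_e: int
    n: int = 1
    last: Match | None = field(default=None, repr=False)

    @property
    def a(self) -> int:
        return self.q_e - self.q_s

    @property
    def b(self) -> int:
        return self.r_e - self.r_s

    @property
    def score(self) -> int:
        return score_merged(self)


@dataclass(frozen=True)
class MapParams:
    """Knobs of the mapping stage."""

    rescue_level: float = 2.0       # R; relative multiplier on A by default
    rescue_absolute: bool = False   # interpret R as an absolute abundance
    rescue_trigger: float = 0.3     # masked-seed fraction that triggers rescue
    rescue_min_seeds: int = 5
    rescue_hard_cap: int = 1000
    max_candidates: int = 20
    dropoff: float = 0.5


def _seed_matches(seed: Seed, occurrences, k: int) -> list[Match]:
    return [
        Match(rid, rs, rs + off + k, seed.q_s, seed.q_e, seed.orientation)
        for rid, rs, off in occurrences
    ]


def find_matches(seeds: list[Seed], index: StrobeIndex) -> tuple[list[Match], float]:
    """Look up every read seed below the abundance cutoff and apply the
    streaming lowest-d filter: a match is kept iff its d does not exceed the
    running minimum observed so far (which it then updates).  This keeps
    early prefix-minimum matches, unlike a two-pass global-minimum filter.

    Returns (matches, fraction of seed instances that were masked).
    """
    k = index.profile.k
    matches: list[Match] = []
    masked = 0
    min_d = math.inf
    for seed in seeds:
        status, occ = index.lookup(seed.hash)
        if status is LookupStatus.MASKED:
            masked += 1
            continue
        for m in _seed_matches(seed, occ, k):
            if m.d <= min_d:
                min_d = m.d
                matches.append(m)
    frac = masked / len(seeds) if seeds else 0.0
    return matches, frac


def rescue_candidates(seeds: list[Seed], index: StrobeIndex, params: MapParams) -> list[Match]:
    """Relaxed-threshold seed retrieval for reads whose seeds were mostly
    masked.  Seeds are sorted by reference abundance; those below R*A (or the
    absolute R) qualify, and if fewer than ``rescue_min_seeds`` do, the hard
    abundance cap (1000) is used instead.  The same streaming lowest-d filter
    is then applied in abundance order."""
    k = index.profile.k
    with_abund = [(index.count(s.hash), i, s) for i, s in enumerate(seeds)]
    with_abund = [(a, i, s) for a, i, s in with_abund if a > 0]
    with_abund.sort(key=lambda t: (t[0], t[1]))
    if params.rescue_absolute:
        threshold = params.rescue_level
    else:
        threshold = params.rescue_level * index.filter_cutoff
    chosen = [(a, s) for a, _, s in with_abund if a < threshold]
    if len(chosen) < params.rescue_min_seeds:
        chosen = [(a, s) for a, _, s in with_abund if a < params.rescue_hard_cap]
    matches: list[Match] = []
    min_d = math.inf
    for abund, seed in chosen:
        _, occ = index.lookup(seed.hash, max_count=abund)
        for m in _seed_matches(seed, occ, k):
            if m.d <= min_d:
                min_d = m.d
                matches.append(m)
    return matches


def _order_consistent(m: Match, mp: Match) -> bool:
    """Condition (iv): the four strobes appear in the same (staggered or
    nested) order on query and reference."""
    staggered = (m.q_s < mp.q_s < m.q_e < mp.q_e) and (m.r_s < mp.r_s < m.r_e < mp.r_e)
    nested = (m.q_s < mp.q_s < mp.q_e < m.q_e) and (m.r_s < mp.r_s < mp.r_e < m.r_e)
    return staggered or nested


def _joins(m: Match, mp: Match) -> bool:
    return (
        m.r_id == mp.r_id
        and m.o == mp.o
        and m.q_s < mp.q_s <= m.q_e
        and m.r_s < mp.r_s <= m.r_e
        and _order_consistent(m, mp)
    )


def merge_matches(matches: list[Match]) -> list[MergedMatch]:
    """Sweep over matches in ascending read order, maintaining open merged
    matches; a match joins the first open merged match whose most recently
    added match satisfies conditions (i)-(iv), else it opens a new one.
    Merged matches close once the sweep passes their rightmost query end.

    Input must be sorted by q_s (duplicates are ignored); raises on unsorted
    input.
    """
    if any(matches[i].q_s > matches[i + 1].q_s for i in range(len(matches) - 1)):
        raise ValueError("matches must be sorted in ascending order in the read")
    seen: set[Match] = set()
    open_mms: list[MergedMatch] = []
    closed: list[MergedMatch] = []
    for m in matches:
        if m in seen:
            continue
        seen.add(m)
        still_open = []
        for mm in open_mms:
            (closed if mm.q_e < m.q_s else still_open).append(mm)
        open_mms = still_open
        for mm in open_mms:
            if _joins(mm.last, m):
                mm.n += 1
                mm.q_e = max(mm.q_e, m.q_e)
                mm.r_e = max(mm.r_e, m.r_e)
                mm.last = m
                break
        else:
            open_mms.append(
                MergedMatch(m.r_id, m.o, m.q_s, m.q_e, m.r_s, m.r_e, n=1, last=m)
            )
    closed.extend(open_mms)
    return closed


def score_merged(mm: MergedMatch) -> int:
    """S_M = (min{a, b} - |a - b|) * n; may be negative when the spans on
    query and reference disagree badly."""
    a, b = mm.a, mm.b
    return (min(a, b) - abs(a - b)) * mm.n


def mapq(s1: float, s2: float, n_top: int) -> int:
    """MAPQ = 40 * (1 - S2/S1) * min{1, n/10} * ln(S1), floored and clamped
    to [0, 60]; S1 <= 0 yields 0."""
    if s1 <= 0:
        return 0
    val = 40.0 * (1.0 - s2 / s1) * min(1.0, n_top / 10.0) * math.log(s1)
    return max(0, min(60, int(val)))


def candidate_regions(
    read: str, index: StrobeIndex, params: MapParams = MapParams()
) -> tuple[list[MergedMatch], float]:
    """Full mapping-stage pipeline for one read: seeds, matched and filtered
    against the index (with rescue when more than ``rescue_trigger`` of the
    seeds were masked), merged, scored, and sorted by descending S_M (ties by
    (r_id, r_s)).  Returns (candidates, masked fraction)."""
    seeds = read_seeds(read, index.profile)
    matches, masked_frac = find_matches(seeds, index)
    if masked_frac > params.rescue_trigger:
        matches = rescue_candidates(seeds, index, params)
    matches.sort(key=lambda m: (m.q_s, m.r_id, m.o, m.r_s))
    merged = merge_matches(matches)
    merged.sort(key=lambda mm: (-mm.score, mm.r_id, mm.r_s))
    return merged, masked_frac


@dataclass
class MappingRecord:
    """One line of the extension-free (PAF-like) mapping output."""

    query_name: str
    query_len: int
    q_s: int = 0
    q_e: int = 0
    strand: str = "*"
    ref_name: str = "*"
    ref_len: int = 0
    r_s: int = 0
    r_e: int = 0
    n_matches: int = 0
    score: int = 0
    mapq: int = 0
    is_mapped: bool = False

    def to_tsv(self) -> str:
        return "\t".join(
            str(v)
            for v in (
                self.query_name, self.query_len, self.q_s, self.q_e, self.strand,
                self.ref_name, self.ref_len, self.r_s, self.r_e,
                self.n_matches, self.score, self.mapq,
            )
        )


def map_extension_free(
    read_name: str, read: str, index: StrobeIndex, params: MapParams = MapParams()
) -> MappingRecord:
    """Report the best-scoring merged match without base-level alignment."""
    cands, _ = candidate_regions(read, index, params)
    rec = MappingRecord(query_name=read_name, query_len=len(read))
    if not cands:
        return rec
    best = cands[0]
    s1 = best.score
    s2 = cands[1].score if len(cands) > 1 else 0
    rec = replace(
        rec,
        q_s=best.q_s,
        q_e=best.q_e,
        strand="-" if best.o else "+",
        ref_name=index.ref_names[best.r_id],
        ref_len=index.ref_lengths[best.r_id],
        r_s=best.r_s,
        r_e=best.r_e,
        n_matches=best.n,
        score=s1,
        mapq=mapq(s1, max(s2, 0), best.n),
        is_mapped=True,
    )
    return rec
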