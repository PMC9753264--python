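"""File-level orchestration: FASTQ streams in, SAM / PAF-like lines out.

Paired-end alignment happens in two phases: a first pass over up to the
first 500 read pairs collects fragment lengths from pairs where both mates
have a unique best merged match on the same reference in FR orientation;
the insert-size model is frozen from those observations (with documented
defaults when fewer than 100 qualify) before any alignment is emitted.
"""

from __future__ import annotations

import statistics
from pathlib import Path
from typing import Iterable, Iterator

import pysam

from .alignment import (
    InsertSizeModel,
    MapParams,
    ScoringParams,
    align_paired,
    align_single,
    estimate_insert_size,
    _pair_geometry,
)
from .index import StrobeIndex
from .mapping import candidate_regions, map_extension_free
from .samio import sam_pair, sam_single

__all__ = [
    "iter_fastq",
    "median_read_length",
    "align_single_stream",
    "align_paired_stream",
    "map_stream",
    "estimate_insert_from_pairs",
]

Read = tuple[str, str, str]  # (name, seq, qual)


def iter_fastq(path: str | Path) -> Iterator[Read]:
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            yield rec.name, rec.sequence.upper(), rec.quality or "I" * len(rec.sequence)


def median_read_length(path: str | Path, n: int = 500) -> int:
    """Median length of the first ``n`` reads (even count: mean of the middle
    pair, rounded to int when integral)."""
    lengths = []
    for i, (_, seq, _) in enumerate(iter_fastq(path)):
        if i >= n:
            break
        lengths.append(len(seq))
    if not lengths:
        raise ValueError(f"no reads in {path}")
    med = statistics.median(lengths)
    return int(med) if float(med).is_integer() else int(round(med))


def align_single_stream(
    reads: Iterable[Read],
    index: StrobeIndex,
    params: MapParams = MapParams(),
    scoring: ScoringParams = ScoringParams(),
) -> Iterator[str]:
    for name, seq, qual in reads:
        res = align_single(seq, index, params, scoring)
        yield sam_single(name, res, index, seq, qual)


def estimate_insert_from_pairs(
    pairs: list[tuple[Read, Read]],
    index: StrobeIndex,
    params: MapParams = MapParams(),
    max_obs: int = 500,
) -> InsertSizeModel:
    """Fragment-length model from concordant unique-best pairs among the
    first ``max_obs`` observations."""
    obs: list[float] = []
    for (n1, s1, _), (n2, s2, _) in pairs:
        if len(obs) >= max_obs:
            break
        c1, _ = candidate_regions(s1, index, params)
        c2, _ = candidate_regions(s2, index, params)
        if not c1 or not c2:
            continue
        if len(c1) > 1 and c1[0].score <= c1[1].score:
            continue
        if len(c2) > 1 and c2[0].score <= c2[1].score:
            continue
        fr, _ = _pair_geometry(c1[0], c2[0])
        if fr:
            # extrapolate the merged-match span to the full read span
            fwd, rev = (c1[0], c2[0]) if c1[0].o == 0 else (c2[0], c1[0])
            len_f, len_r = (len(s1), len(s2)) if c1[0].o == 0 else (len(s2), len(s1))
            obs.append(float((rev.r_e + (len_r - rev.q_e)) - (fwd.r_s - fwd.q_s)))
    return estimate_insert_size(obs, max_obs=max_obs)


def align_paired_stream(
    pairs: list[tuple[Read, Read]],
    index: StrobeIndex,
    params: MapParams = MapParams(),
    scoring: ScoringParams = ScoringParams(),
    model: InsertSizeModel | None = None,
) -> tuple[InsertSizeModel, Iterator[str]]:
    if model is None:
        model = estimate_insert_from_pairs(pairs, index, params)

    def gen() -> Iterator[str]:
        for (n1, s1, q1), (_, s2, q2) in pairs:
            r1, r2 = align_paired(s1, s2, index, model, params, scoring)
            l1, l2 = sam_pair(n1, r1, r2, index, s1, q1, s2, q2, model)
            yield l1
            yield l2

    return model, gen()


def map_stream(
    reads: Iterable[Read],
    index: StrobeIndex,
    params: MapParams = MapParams(),
) -> Iterator[str]:
    """Extension-free mapping: one PAF-like TSV line per read."""
    for name, seq, _ in reads:
        yield map_extension_free(name, seq, index, params).to_tsv()
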