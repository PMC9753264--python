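"""Seed-repetitiveness statistics.

E-hits is the expected occurrence count of a seed drawn uniformly from the
multiset of reference seeds: with x_i the count of distinct seed i and
N = sum x_i, E-hits = (1/N) * sum x_i^2.  Under uniform read sampling this
equals the expected number of reference hits of an error-free seed extracted
from a read.  The hard-masked fraction is the fraction of seed instances
whose hash occurs more than a threshold number of times (default 1000).

``census_of`` builds the count distribution for k-mers, window minimizers,
open syncmers, or randstrobe seeds so the schemes can be compared on the
same sequence.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .nucleo import PackedSeq, canonical_hashes, sample_minimizers
from .seeding import SeedProfile, SyncmerParams, open_syncmers, reference_seed_arrays

__all__ = ["SeedCensus", "ehits", "hard_masked_fraction", "census_of"]


@dataclass
class SeedCensus:
    """Occurrence counts of distinct seed hashes: N total instances, M
    distinct.  ``median_span`` is populated for variable-length randstrobe
    seeds only."""

    counts: Counter = field(default_factory=Counter)
    median_span: float | None = None

    @property
    def N(self) -> int:
        return sum(self.counts.values())

    @property
    def M(self) -> int:
        return len(self.counts)

    @classmethod
    def from_hashes(cls, hashes: np.ndarray, median_span: float | None = None) -> "SeedCensus":
        uniq, cnt = np.unique(np.asarray(hashes, dtype=np.uint64), return_counts=True)
        return cls(Counter(dict(zip(map(int, uniq), map(int, cnt)))), median_span)


def ehits(census: SeedCensus) -> float:
    """E-hits = (1/N) * sum x_i^2; equals 1 iff all seeds are unique."""
    n = census.N
    if n < 1:
        raise ValueError("empty seed census")
    return sum(x * x for x in census.counts.values()) / n


def hard_masked_fraction(census: SeedCensus, threshold: int = 1000) -> float:
    """Fraction of seed *instances* whose hash occurs strictly more than
    ``threshold`` times (instance-weighted)."""
    n = census.N
    if n < 1:
        raise ValueError("empty seed census")
    return sum(x for x in census.counts.values() if x > threshold) / n


def census_of(seq: str | PackedSeq, method: str, params: dict | None = None) -> SeedCensus:
    """Seed census of one sequence under a named seeding scheme.

    method: "kmers" (params: k), "minimizers" (k, w), "syncmers" (k, s, and
    optionally t; central by default), or "randstrobes" (profile:
    SeedProfile).  All schemes use canonical hashing.
    """
    params = dict(params or {})
    ps = seq if isinstance(seq, PackedSeq) else PackedSeq.from_str(seq)
    if method == "kmers":
        k = params["k"]
        h, valid = canonical_hashes(ps, k)
        return SeedCensus.from_hashes(h[valid])
    if method == "minimizers":
        mins = sample_minimizers(ps, params["k"], params["w"])
        return SeedCensus.from_hashes(np.array([h for _, h in mins], dtype=np.uint64))
    if method == "syncmers":
        k, s = params["k"], params["s"]
        sp = SyncmerParams(k, s, params["t"]) if "t" in params else SyncmerParams.central(k, s)
        return SeedCensus.from_hashes(open_syncmers(ps, sp).hashes)
    if method == "randstrobes":
        profile: SeedProfile = params["profile"]
        seeds = reference_seed_arrays(ps, profile)
        spans = seeds.q_e - seeds.q_s
        med = float(np.median(spans)) if len(seeds) else None
        return SeedCensus.from_hashes(seeds.hash, median_span=med)
    raise ValueError(f"unknown seeding method {method!r}")
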