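"""Canonical open-syncmer extraction and randstrobe linking.

The seeding pipeline subsamples k-mers with the open-syncmer rule (a k-mer is
kept iff the minimum-hash s-mer among its k-s+1 constituent s-mers sits at a
fixed offset t), then links pairs of downstream syncmers into variable-length
strobemer seeds.  Linking uses a skewed sampling function that minimizes the
popcount of the masked XOR of the two strobe hashes, which biases the choice
toward nearby strobes; the stored seed hash h' = h1/2 + h2/2 is symmetric so
that forward and reverse-complement construction give the same value.

With k-s+1 odd and t central, the same syncmer positions are selected on both
strands, which together with canonical s-mer/k-mer hashing makes the whole
seed set strand-symmetric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .nucleo import PackedSeq, canonical_hashes, hash64_array, rolling_kmers

__all__ = [
    "SyncmerParams",
    "Syncmer",
    "SyncmerSet",
    "SeedProfile",
    "Seed",
    "SeedArray",
    "FORWARD",
    "REVERSE",
    "open_syncmers",
    "link_randstrobe_sum",
    "link_randstrobe_skew",
    "strobemer_hash",
    "reference_seeds",
    "read_seeds",
    "choose_profile",
    "PROFILE_TABLE",
]

FORWARD = 0
REVERSE = 1

_U = np.uint64
_SENTINEL = np.uint64(0xFFFFFFFFFFFFFFFF)


def _leftmost_mask(p: int) -> np.uint64:
    """64-bit mask with 1s at the p leftmost bits."""
    if not 1 <= p <= 64:
        raise ValueError("p must be in [1, 64]")
    return _U(0xFFFFFFFFFFFFFFFF) << _U(64 - p) & _U(0xFFFFFFFFFFFFFFFF)


@dataclass(frozen=True)
class SyncmerParams:
    """Open-syncmer parameters (k, s, t); t is the 1-based offset at which the
    minimum s-mer must sit.  k-s+1 odd with central t = ceil((k-s+1)/2) gives
    strand-symmetric selection."""

    k: int = 20
    s: int = 16
    t: int = 3

    def __post_init__(self):
        if not 1 <= self.s <= self.k:
            raise ValueError("require 1 <= s <= k")
        if not 1 <= self.t <= self.k - self.s + 1:
            raise ValueError("t must be within [1, k-s+1]")

    @classmethod
    def central(cls, k: int, s: int) -> "SyncmerParams":
        return cls(k=k, s=s, t=math.ceil((k - s + 1) / 2))


@dataclass(frozen=True)
class Syncmer:
    pos: int
    hash: int


class SyncmerSet:
    """Selected syncmers of one sequence, held as parallel numpy arrays
    (positions strictly increasing) with list-like access."""

    def __init__(self, pos: np.ndarray, hashes: np.ndarray, k: int):
        self.pos = pos
        self.hashes = hashes
        self.k = k

    def __len__(self) -> int:
        return self.pos.size

    def __getitem__(self, i: int) -> Syncmer:
        return Syncmer(int(self.pos[i]), int(self.hashes[i]))

    def __iter__(self):
        for p, h in zip(self.pos, self.hashes):
            yield Syncmer(int(p), int(h))


def open_syncmers(seq: str | PackedSeq, params: SyncmerParams) -> SyncmerSet:
    """Scan all decodable k-mers and keep those whose minimum canonical-hash
    s-mer sits at offset t (1-based; ties broken toward the smallest offset).
    The emitted hash is the canonical k-mer hash."""
    ps = seq if isinstance(seq, PackedSeq) else PackedSeq.from_str(seq)
    k, s, t = params.k, params.s, params.t
    kh, kvalid = canonical_hashes(ps, k)
    if kh.size == 0:
        return SyncmerSet(np.empty(0, np.int64), np.empty(0, np.uint64), k)
    sh, svalid = canonical_hashes(ps, s)
    sh = np.where(svalid, sh, _SENTINEL)
    nsmer = k - s + 1
    windows = np.lib.stride_tricks.sliding_window_view(sh, nsmer)[: kh.size]
    selected = kvalid & (np.argmin(windows, axis=1) == t - 1)
    pos = np.flatnonzero(selected).astype(np.int64)
    return SyncmerSet(pos, kh[pos], k)


def link_randstrobe_sum(k1_hash: int, window: list[int], p: int) -> int:
    """Reference (unskewed) randstrobe link: argmin over the window of
    (h(k1) + h(k')) & mask, mask = p leftmost bits; leftmost wins ties.
    Provided for comparison only — indexing uses the skewed rule."""
    if not window:
        raise ValueError("no candidate strobes in window")
    mask = _leftmost_mask(p)
    w = np.asarray(window, dtype=np.uint64)
    vals = (_U(k1_hash) + w) & mask
    return int(np.argmin(vals))


def link_randstrobe_skew(k1_hash: int, window: list[int], p: int) -> int:
    """Skewed randstrobe link: argmin over the window of the number of set
    bits of (h(k1) XOR h(k')) & mask among the p leftmost bits.  The value
    space collapses to [0, p], so collisions are frequent and resolve to the
    first (leftmost) strobe — skewing the choice toward nearby strobes."""
    if not window:
        raise ValueError("no candidate strobes in window")
    mask = _leftmost_mask(p)
    w = np.asarray(window, dtype=np.uint64)
    costs = np.bitwise_count((_U(k1_hash) ^ w) & mask)
    return int(np.argmin(costs))


def strobemer_hash(h1: int, h2: int) -> int:
    """Symmetric strobemer hash h' = floor(h1/2) + floor(h2/2); identical for
    (h1, h2) and (h2, h1), never exceeds 64 bits."""
    return (int(h1) >> 1) + (int(h2) >> 1)


# ---------------------------------------------------------------------------
# read-length dependent parameter profiles

@dataclass(frozen=True)
class SeedProfile:
    """Seeding parameters: strobe length k, inner s-mer length s, skew-mask
    width p (bits), and the count-based syncmer window [w_min, w_max]
    derived from offsets l and u via w = k/(k-s+1) + l (resp. u).
    ``max_seed_len`` caps the seed span in bases (default: median read
    length - 50)."""

    k: int
    s: int
    p: int
    l: int
    u: int
    max_seed_len: int

    @property
    def s_delta(self) -> int:
        return self.k - self.s

    @property
    def w_min(self) -> int:
        return max(1, self.k // (self.k - self.s + 1) + self.l)

    @property
    def w_max(self) -> int:
        return max(self.w_min, self.k // (self.k - self.s + 1) + self.u)

    @property
    def syncmer_params(self) -> SyncmerParams:
        return SyncmerParams.central(self.k, self.s)

    def __post_init__(self):
        if not 1 <= self.p <= 64:
            raise ValueError("p must be in [1, 64]")
        if self.max_seed_len < self.k + 1:
            object.__setattr__(self, "max_seed_len", self.k + 1)

    # small key=value text round-trip for config files
    def to_config(self) -> str:
        return "".join(
            f"{f}={getattr(self, f)}\n" for f in ("k", "s", "p", "l", "u", "max_seed_len")
        )

    @classmethod
    def from_config(cls, text: str) -> "SeedProfile":
        kv = dict(line.split("=", 1) for line in text.strip().splitlines())
        return cls(**{key: int(v) for key, v in kv.items()})


#: (upper median-read-length bound, k, s_delta, p, l, u); the second element
#: is k - s, so (20, 4, ...) means s = 16.
PROFILE_TABLE: list[tuple[float, int, int, int, int, int]] = [
    (75, 20, 4, 8, -4, 2),
    (125, 20, 4, 8, -2, 2),
    (175, 20, 4, 8, 1, 7),
    (275, 20, 4, 8, 4, 13),
    (375, 22, 4, 8, 2, 12),
    (math.inf, 23, 6, 8, 2, 12),
]


def choose_profile(median_read_len: int) -> SeedProfile:
    """Pick the (k, s, p, l, u) tuple for the given median read length x~;
    max_seed_len defaults to x~ - 50, floored at k + 1."""
    if median_read_len < 1:
        raise ValueError("median read length must be >= 1")
    for upper, k, s_delta, p, l, u in PROFILE_TABLE:
        if median_read_len <= upper:
            return SeedProfile(
                k=k, s=k - s_delta, p=p, l=l, u=u,
                max_seed_len=max(median_read_len - 50, k + 1),
            )
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# seed construction

@dataclass(frozen=True)
class Seed:
    """A strobemer seed: symmetric hash, [q_s, q_e) span on the source
    sequence (forward coordinates), second-strobe offset, orientation, and
    whether the single-syncmer fallback was used."""

    hash: int
    q_s: int
    q_e: int
    offset: int
    orientation: int = FORWARD
    is_single: bool = False


@dataclass
class SeedArray:
    """Struct-of-arrays seed container used on the reference path."""

    hash: np.ndarray          # uint64
    q_s: np.ndarray           # int64, start of first strobe
    q_e: np.ndarray           # int64, end (exclusive) of second strobe
    offset: np.ndarray        # int64, second-strobe start - first-strobe start
    is_single: np.ndarray     # bool
    orientation: int = FORWARD
    n_offset_truncated: int = 0   # diagnostic: linked seeds demoted to fallback

    def __len__(self) -> int:
        return self.hash.size

    def to_seeds(self) -> list[Seed]:
        return [
            Seed(int(h), int(a), int(b), int(o), self.orientation, bool(sg))
            for h, a, b, o, sg in zip(self.hash, self.q_s, self.q_e, self.offset, self.is_single)
        ]


def _link(pos: np.ndarray, hashes: np.ndarray, profile: SeedProfile) -> SeedArray:
    """Vectorized skewed linking over a syncmer list in iteration order.

    For syncmer j the candidate window is syncmers j+w_min .. j+w_max,
    truncated to those whose span fits max_seed_len; empty windows emit the
    single-syncmer fallback seed (h'(k1, k1)).
    """
    n = pos.size
    k = profile.k
    if n == 0:
        z = np.empty(0, np.int64)
        return SeedArray(np.empty(0, np.uint64), z, z.copy(), z.copy(), np.empty(0, bool))
    offs = np.arange(profile.w_min, profile.w_max + 1)
    idx = np.arange(n)[:, None] + offs[None, :]
    in_range = idx < n
    idxc = np.minimum(idx, n - 1)
    span_ok = pos[idxc] + k - pos[:, None] <= profile.max_seed_len
    valid = in_range & span_ok
    mask = _leftmost_mask(profile.p)
    cost = np.bitwise_count((hashes[:, None] ^ hashes[idxc]) & mask).astype(np.uint16)
    cost = np.where(valid, cost, np.uint16(999))
    choice = np.argmin(cost, axis=1)
    rows = np.arange(n)
    linked = valid[rows, choice]
    j2 = np.where(linked, idxc[rows, choice], rows)
    offset = pos[j2] - pos
    too_far = linked & (offset > 255)
    n_trunc = int(too_far.sum())
    if n_trunc:
        linked = linked & ~too_far
        j2 = np.where(linked, j2, rows)
        offset = pos[j2] - pos
    seed_hash = (hashes >> _U(1)) + (hashes[j2] >> _U(1))
    return SeedArray(
        hash=seed_hash,
        q_s=pos.astype(np.int64),
        q_e=(pos[j2] + k).astype(np.int64),
        offset=offset.astype(np.int64),
        is_single=~linked,
        n_offset_truncated=n_trunc,
    )


def reference_seed_arrays(seq: str | PackedSeq, profile: SeedProfile) -> SeedArray:
    sset = open_syncmers(seq, profile.syncmer_params)
    return _link(sset.pos, sset.hashes, profile)


def reference_seeds(seq: str | PackedSeq, profile: SeedProfile) -> list[Seed]:
    """Forward-direction strobemer seeds of a reference sequence."""
    return reference_seed_arrays(seq, profile).to_seeds()


def read_seed_arrays(read: str | PackedSeq, profile: SeedProfile) -> tuple[SeedArray, SeedArray]:
    """Seeds of a read in both orientations.

    Canonical syncmers are computed once; forward seeds link syncmers in
    forward order, reverse-orientation seeds in reverse order.  Coordinates
    (q_s, q_e) of reverse-orientation seeds are on the reverse-complemented
    read, so that matches on either strand run collinear with the reference
    and chain under the merge conditions.
    """
    ps = read if isinstance(read, PackedSeq) else PackedSeq.from_str(read)
    L = ps.length
    sset = open_syncmers(ps, profile.syncmer_params)
    k = profile.k
    fwd = _link(sset.pos, sset.hashes, profile)
    # reverse orientation: positions on the reverse-complement read axis
    rpos = (L - k) - sset.pos[::-1]
    rev = _link(np.ascontiguousarray(rpos), np.ascontiguousarray(sset.hashes[::-1]), profile)
    rev.orientation = REVERSE
    return fwd, rev


def read_seeds(read: str | PackedSeq, profile: SeedProfile) -> list[Seed]:
    fwd, rev = read_seed_arrays(read, profile)
    return fwd.to_seeds() + rev.to_seeds()
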