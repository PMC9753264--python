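"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (string materialization, exhaustive
scans, full dynamic programming) and shares no code path with the package
beyond the scalar primitives it is checking against.
"""

from __future__ import annotations

import math

from randalign.nucleo import encode_kmer, hash64, revcomp


def invert_xorshift(z: int, r: int) -> int:
    """Invert x ^= x >> r over 64 bits."""
    res = z
    for _ in range(64 // r + 1):
        res = z ^ (res >> r)
    return res & 0xFFFFFFFFFFFFFFFF


_INV1 = pow(0xBF58476D1CE4E5B9, -1, 1 << 64)
_INV2 = pow(0x94D049BB133111EB, -1, 1 << 64)


def inverse_mixer(z: int) -> int:
    """Inverse of the splitmix64 finalizer used as hash64."""
    z = invert_xorshift(z, 31)
    z = (z * _INV2) & 0xFFFFFFFFFFFFFFFF
    z = invert_xorshift(z, 27)
    z = (z * _INV1) & 0xFFFFFFFFFFFFFFFF
    z = invert_xorshift(z, 30)
    return z


def canonical_hash_str(kmer: str) -> int:
    """Canonical k-mer hash computed from strings."""
    fwd = encode_kmer(kmer)
    rc = encode_kmer(revcomp(kmer))
    return hash64(min(fwd, rc))


def syncmer_positions_str(seq: str, k: int, s: int, t: int) -> list[int]:
    """String-based open-syncmer scan: materialize every s-mer, hash the
    canonical form, select k-mers whose minimum sits at offset t (1-based,
    ties toward the smallest offset)."""
    out = []
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if any(c not in "ACGT" for c in kmer):
            continue
        smers = [canonical_hash_str(kmer[j : j + s]) for j in range(k - s + 1)]
        if smers.index(min(smers)) == t - 1:
            out.append(i)
    return out


def minimizers_brute(seq: str, k: int, w: int) -> list[int]:
    """Per-window argmin scan over canonical k-mer hashes."""
    n = len(seq) - k + 1
    hashes = []
    for i in range(n):
        kmer = seq[i : i + k]
        hashes.append(canonical_hash_str(kmer) if all(c in "ACGT" for c in kmer) else None)
    picked = set()
    ww = min(w, n)
    for start in range(n - ww + 1):
        window = [(h, i) for i, h in enumerate(hashes[start : start + ww], start) if h is not None]
        if window:
            picked.add(min(window)[1])
    return sorted(picked)


def popcount_masked(x: int, p: int) -> int:
    mask = ((1 << p) - 1) << (64 - p)
    return bin(x & mask).count("1")


def link_skew_brute(h1: int, window: list[int], p: int) -> int:
    costs = [popcount_masked(h1 ^ h, p) for h in window]
    return costs.index(min(costs))


def link_sum_brute(h1: int, window: list[int], p: int) -> int:
    mask = ((1 << p) - 1) << (64 - p)
    vals = [((h1 + h) & 0xFFFFFFFFFFFFFFFF) & mask for h in window]
    return vals.index(min(vals))


def reference_seeds_brute(
    positions: list[int], hashes: list[int], k: int, w_min: int, w_max: int,
    p: int, max_seed_len: int,
) -> list[tuple[int, int, int, bool]]:
    """Per-syncmer replay of the skewed linking rule; returns
    (hash, q_s, q_e, is_single) tuples."""
    n = len(positions)
    out = []
    for j in range(n):
        cands = [
            i for i in range(j + w_min, min(j + w_max + 1, n))
            if positions[i] + k - positions[j] <= max_seed_len and positions[i] - positions[j] <= 255
        ]
        if cands:
            pick = cands[link_skew_brute(hashes[j], [hashes[i] for i in cands], p)]
            h = (hashes[j] >> 1) + (hashes[pick] >> 1)
            out.append((h, positions[j], positions[pick] + k, False))
        else:
            h = 2 * (hashes[j] >> 1)
            out.append((h, positions[j], positions[j] + k, True))
    return out


def streaming_lowest_d(d_stream: list[int]) -> list[int]:
    """Replay of the streaming lowest-d filter: keep a match iff its d does
    not exceed the running minimum (which it then updates)."""
    kept, best = [], math.inf
    for i, d in enumerate(d_stream):
        if d <= best:
            best = d
            kept.append(i)
    return kept


def smith_waterman_score(
    query: str, target: str, match: int = 1, mismatch: int = 4,
    gap_open: int = 6, gap_extend: int = 1,
) -> int:
    """Textbook affine-gap local alignment score (three-state DP); a gap of
    length l costs gap_open + (l-1)*gap_extend."""
    n, m = len(query), len(target)
    NEG = -(10 ** 9)
    best = 0
    prev_m = [0] * (m + 1)
    prev_x = [NEG] * (m + 1)
    prev_y = [NEG] * (m + 1)
    for i in range(1, n + 1):
        cur_m = [0] * (m + 1)
        cur_x = [NEG] * (m + 1)
        cur_y = [NEG] * (m + 1)
        for j in range(1, m + 1):
            s = match if query[i - 1] == target[j - 1] else -mismatch
            cur_m[j] = max(0, s + max(prev_m[j - 1], prev_x[j - 1], prev_y[j - 1]))
            # gap in target (query base consumed)
            cur_x[j] = max(prev_m[j] - gap_open, prev_x[j] - gap_extend)
            # gap in query (target base consumed)
            cur_y[j] = max(cur_m[j - 1] - gap_open, cur_y[j - 1] - gap_extend)
            best = max(best, cur_m[j])
        prev_m, prev_x, prev_y = cur_m, cur_x, cur_y
    return best


def merge_matches_naive(matches):
    """Independent re-implementation of the merged-match sweep (conditions
    i-iv) used as the replay checker; returns sorted
    (r_id, o, q_s, q_e, r_s, r_e, n) tuples."""

    def joins(m, mp):
        i = m.r_id == mp.r_id and m.o == mp.o
        ii = m.q_s < mp.q_s <= m.q_e
        iii = m.r_s < mp.r_s <= m.r_e
        stag = m.q_s < mp.q_s < m.q_e < mp.q_e and m.r_s < mp.r_s < m.r_e < mp.r_e
        nest = m.q_s < mp.q_s < mp.q_e < m.q_e and m.r_s < mp.r_s < mp.r_e < m.r_e
        return i and ii and iii and (stag or nest)

    groups = []  # [extremes, last_match, open?]
    dedup = []
    seen = set()
    for m in matches:
        key = (m.r_id, m.o, m.q_s, m.q_e, m.r_s, m.r_e)
        if key not in seen:
            seen.add(key)
            dedup.append(m)
    for m in dedup:
        for g in groups:
            if g[2]:
                g[2] = not (g[0][3] < m.q_s)
        joined = False
        for g in groups:
            if g[2] and joins(g[1], m):
                ext = g[0]
                g[0] = (ext[0], ext[1], ext[2], max(ext[3], m.q_e), ext[4], max(ext[5], m.r_e), ext[6] + 1)
                g[1] = m
                joined = True
                break
        if not joined:
            groups.append([(m.r_id, m.o, m.q_s, m.q_e, m.r_s, m.r_e, 1), m, True])
    return sorted(
        (g[0][0], g[0][1], g[0][2], g[0][3], g[0][4], g[0][5], g[0][6]) for g in groups
    )
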