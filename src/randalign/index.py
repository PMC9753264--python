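"""Flat-vector reference index over strobemer seeds.

Seeds from all references are stored in one vector sorted by hash; a
directory maps each distinct hash to its (offset, count) slice.  Seeds whose
occurrence count exceeds the abundance cutoff A are masked at query time; A
is derived from the top masking fraction f of distinct hashes (default
0.0002, as in minimap2-style repeat masking).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np

from .nucleo import read_fasta
from .seeding import SeedProfile, reference_seed_arrays

__all__ = ["LookupStatus", "IndexRecord", "StrobeIndex", "build_index", "load_index"]

_MAGIC = b"RANDALIGN-IDX-v1\n"
MAX_REFS = 1 << 24
MAX_REF_LEN = (1 << 32) - 1


class LookupStatus(Enum):
    FOUND = 0
    MASKED = 1
    ABSENT = 2


@dataclass(frozen=True)
class IndexRecord:
    """One seed occurrence: hash, 32-bit start of the first strobe, and a
    packed 32-bit field v with the reference id in the rightmost 24 bits and
    the second-strobe offset in the leftmost 8 bits."""

    hash: int
    r_s: int
    v: int

    @property
    def ref_id(self) -> int:
        return self.v & 0xFFFFFF

    @property
    def offset(self) -> int:
        return self.v >> 24


class StrobeIndex:
    """Sorted seed vector + hash directory for one set of references.

    Attributes of interest: ``filter_cutoff`` (A), ``f`` (masking fraction),
    ``profile``, ``ref_names`` / ``ref_lengths`` / ``ref_seqs``.
    """

    def __init__(
        self,
        hashes: np.ndarray,
        r_starts: np.ndarray,
        packed: np.ndarray,
        profile: SeedProfile,
        f: float,
        ref_names: list[str],
        ref_seqs: list[str],
    ):
        self.hashes = hashes            # uint64, sorted
        self.r_starts = r_starts        # uint32
        self.packed = packed            # uint32: offset<<24 | ref_id
        self.profile = profile
        self.f = f
        self.ref_names = ref_names
        self.ref_seqs = ref_seqs
        self.ref_lengths = [len(s) for s in ref_seqs]
        uniq, starts, counts = np.unique(hashes, return_index=True, return_counts=True)
        self.directory: dict[int, tuple[int, int]] = {
            int(h): (int(s), int(c)) for h, s, c in zip(uniq, starts, counts)
        }
        self.filter_cutoff = self._abundance_cutoff(counts, f)

    @staticmethod
    def _abundance_cutoff(counts: np.ndarray, f: float) -> int:
        """A = occurrence count of the distinct hash at descending rank
        ceil(f * #distinct), floored at 2."""
        if counts.size == 0:
            return 2
        desc = np.sort(counts)[::-1]
        rank = max(1, math.ceil(f * desc.size))
        return max(2, int(desc[rank - 1]))

    @property
    def n_seeds(self) -> int:
        return int(self.hashes.size)

    @property
    def n_distinct(self) -> int:
        return len(self.directory)

    def count(self, hash_: int) -> int:
        """Occurrence count of a hash (0 if absent), ignoring masking."""
        entry = self.directory.get(hash_)
        return entry[1] if entry else 0

    def lookup(self, hash_: int, max_count: int | None = None):
        """Query one seed hash.

        Returns (LookupStatus, occurrences); occurrences is a list of
        (ref_id, r_s, offset) tuples when FOUND, else empty.  ``max_count``
        overrides the abundance cutoff A (used by rescue mode).
        """
        entry = self.directory.get(hash_)
        if entry is None:
            return LookupStatus.ABSENT, []
        start, cnt = entry
        cutoff = self.filter_cutoff if max_count is None else max_count
        if cnt > cutoff:
            return LookupStatus.MASKED, []
        return LookupStatus.FOUND, self.occurrences(start, cnt)

    def occurrences(self, start: int, cnt: int) -> list[tuple[int, int, int]]:
        sl = slice(start, start + cnt)
        return [
            (int(v) & 0xFFFFFF, int(rs), int(v) >> 24)
            for rs, v in zip(self.r_starts[sl], self.packed[sl])
        ]

    def records(self) -> list[IndexRecord]:
        return [
            IndexRecord(int(h), int(rs), int(v))
            for h, rs, v in zip(self.hashes, self.r_starts, self.packed)
        ]

    # -- serialization ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Deterministic binary dump: magic, JSON header, then the three
        seed arrays in numpy format."""
        header = {
            "f": self.f,
            "profile": {k: getattr(self.profile, k) for k in ("k", "s", "p", "l", "u", "max_seed_len")},
            "ref_names": self.ref_names,
            "ref_seqs": self.ref_seqs,
        }
        blob = json.dumps(header, sort_keys=True).encode()
        with open(path, "wb") as fh:
            fh.write(_MAGIC)
            fh.write(len(blob).to_bytes(8, "little"))
            fh.write(blob)
            for arr in (self.hashes, self.r_starts, self.packed):
                np.lib.format.write_array(fh, arr, allow_pickle=False)


def load_index(path: str | Path) -> StrobeIndex:
    with open(path, "rb") as fh:
        magic = fh.read(len(_MAGIC))
        if magic != _MAGIC:
            raise ValueError(f"not a randalign index (bad magic in {path})")
        n = int.from_bytes(fh.read(8), "little")
        blob = fh.read(n)
        if len(blob) < n:
            raise ValueError(f"truncated index file {path}")
        header = json.loads(blob)
        try:
            arrays = [np.lib.format.read_array(fh, allow_pickle=False) for _ in range(3)]
        except Exception as exc:  # noqa: BLE001 - normalize to a clear message
            raise ValueError(f"truncated or corrupt index file {path}: {exc}") from exc
    profile = SeedProfile(**header["profile"])
    return StrobeIndex(
        arrays[0], arrays[1], arrays[2], profile, header["f"],
        header["ref_names"], header["ref_seqs"],
    )


def build_index(
    references: list[tuple[str, str]] | str | Path,
    profile: SeedProfile,
    f: float = 0.0002,
) -> StrobeIndex:
    """Build the index from (name, sequence) pairs or a FASTA path.

    Records are sorted by (hash, ref id, r_s) for reproducible builds.
    """
    if isinstance(references, (str, Path)):
        references = list(read_fasta(references))
    references = [(n, s) for n, s in references if len(s) > 0]
    if not references:
        raise ValueError("no non-empty reference sequences")
    if len(references) > MAX_REFS:
        raise ValueError(f"at most {MAX_REFS} references supported (24-bit reference id)")
    hashes, starts, packed = [], [], []
    for rid, (name, seq) in enumerate(references):
        if len(seq) > MAX_REF_LEN:
            raise ValueError(f"reference {name} exceeds the 32-bit coordinate limit")
        seeds = reference_seed_arrays(seq, profile)
        hashes.append(seeds.hash)
        starts.append(seeds.q_s.astype(np.uint32))
        packed.append((seeds.offset.astype(np.uint32) << np.uint32(24)) | np.uint32(rid))
    h = np.concatenate(hashes)
    rs = np.concatenate(starts)
    pk = np.concatenate(packed)
    rid_arr = pk & np.uint32(0xFFFFFF)
    order = np.lexsort((rs, rid_arr, h))
    return StrobeIndex(
        h[order], rs[order], pk[order], profile, f,
        [n for n, _ in references], [s for _, s in references],
    )
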