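"""Low-level nucleotide primitives: 2-bit encoding, canonicalization, hashing,
and window-minimizer sampling.

Conventions
-----------
* 2-bit codes: A=00, C=01, G=10, T=11; the first base of a k-mer occupies the
  most significant two bits, so ``TCA`` encodes to ``0b110100`` = 52.
* All coordinates are 0-based, half-open.  Conversion to 1-based happens only
  when SAM records are written.
* ``hash64`` is a fixed, invertible 64-bit mixing permutation (the finalizer
  of splitmix64).  Bijectivity means distinct k-mer encodings can never
  collide through the mixer itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator

import numpy as np

__all__ = [
    "AmbiguousBaseError",
    "PackedSeq",
    "Strand",
    "encode_kmer",
    "decode_kmer",
    "revcomp",
    "canonical_kmer",
    "hash64",
    "hash64_array",
    "sample_minimizers",
    "read_fasta",
]

_BASES = "ACGT"

# byte -> 2-bit code; 255 marks ambiguous (any non-ACGT IUPAC letter)
_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _CODE_LUT[ord(_b)] = _i
    _CODE_LUT[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)
_IUPAC = set("ACGTRYSWKMBDHVNacgtryswkmbdhvn")


class AmbiguousBaseError(ValueError):
    """A k-mer window contained a non-ACGT base and cannot be 2-bit encoded."""


class Strand(Enum):
    FORWARD = 0
    REVERSE = 1


@dataclass
class PackedSeq:
    """A nucleotide sequence held as per-base 2-bit codes.

    ``codes`` stores one 2-bit code per byte (vector-friendly); ambiguous
    bases carry code 0 and are recorded in ``ambiguous_runs`` as disjoint,
    sorted [start, end) intervals.
    """

    length: int
    codes: np.ndarray
    ambiguous_runs: list[tuple[int, int]] = field(default_factory=list)

    @classmethod
    def from_str(cls, seq: str) -> "PackedSeq":
        raw = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
        codes = _CODE_LUT[raw]
        bad = codes == 255
        runs: list[tuple[int, int]] = []
        if bad.any():
            edges = np.flatnonzero(np.diff(np.concatenate(([0], bad.view(np.uint8), [0]))))
            runs = [(int(s), int(e)) for s, e in zip(edges[::2], edges[1::2])]
            codes = np.where(bad, np.uint8(0), codes)
        return cls(length=len(seq), codes=codes, ambiguous_runs=runs)

    def is_ambiguous(self) -> np.ndarray:
        mask = np.zeros(self.length, dtype=bool)
        for s, e in self.ambiguous_runs:
            mask[s:e] = True
        return mask

    def decode(self) -> str:
        """Inverse of :meth:`from_str` for ACGT-only input; ambiguous
        positions decode to ``N``."""
        chars = np.frombuffer(_BASES.encode(), dtype=np.uint8)[self.codes]
        out = chars.copy()
        for s, e in self.ambiguous_runs:
            out[s:e] = ord("N")
        return out.tobytes().decode("ascii")


def encode_kmer(seq: str, start: int = 0, k: int | None = None) -> int:
    """Encode ``seq[start:start+k]`` as a 2k-bit integer (first base most
    significant).  Raises :class:`AmbiguousBaseError` on non-ACGT bases and
    :class:`IndexError` when the window exceeds the sequence."""
    if k is None:
        k = len(seq) - start
    if start < 0 or k < 1 or start + k > len(seq):
        raise IndexError(f"k-mer window [{start}, {start + k}) outside sequence of length {len(seq)}")
    x = 0
    for ch in seq[start : start + k]:
        c = _CODE_LUT[ord(ch)]
        if c == 255:
            raise AmbiguousBaseError(f"undecodable k-mer: non-ACGT base {ch!r}")
        x = (x << 2) | int(c)
    return x


def decode_kmer(x: int, k: int) -> str:
    return "".join(_BASES[(x >> (2 * (k - 1 - i))) & 3] for i in range(k))


def revcomp(seq: str) -> str:
    """Reverse complement; IUPAC ambiguity codes map to their complements."""
    bad = set(seq) - _IUPAC
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmer(x_fwd: int, x_rc: int) -> tuple[int, Strand]:
    """Return the numerically smaller of a k-mer's forward and
    reverse-complement encodings (2-bit order == lexicographic order), with
    the strand that supplied it; palindromes report forward."""
    if x_rc < x_fwd:
        return x_rc, Strand.REVERSE
    return x_fwd, Strand.FORWARD


_C1 = np.uint64(0xBF58476D1CE4E5B9)
_C2 = np.uint64(0x94D049BB133111EB)
_U = np.uint64


def hash64_array(x: np.ndarray) -> np.ndarray:
    """Vectorized invertible 64-bit mixer (splitmix64 finalizer)."""
    x = x.astype(np.uint64, copy=True)
    x ^= x >> _U(30)
    x *= _C1
    x ^= x >> _U(27)
    x *= _C2
    x ^= x >> _U(31)
    return x


def hash64(x: int) -> int:
    """Scalar invertible 64-bit mixer; bijective over [0, 2^64)."""
    return int(hash64_array(np.array([x], dtype=np.uint64))[0])


# ---------------------------------------------------------------------------
# rolling k-mer machinery shared by minimizers / syncmers / seed statistics

def rolling_kmers(ps: PackedSeq, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward and reverse-complement 2-bit encodings for every k-mer start,
    plus a validity mask (False where the window touches an ambiguous base).

    Returns empty arrays when the sequence is shorter than k.
    """
    n = ps.length - k + 1
    if n <= 0:
        e = np.empty(0, dtype=np.uint64)
        return e, e.copy(), np.empty(0, dtype=bool)
    c = ps.codes.astype(np.uint64)
    comp = _U(3) - c
    fwd = np.zeros(n, dtype=np.uint64)
    rc = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        fwd |= c[j : j + n] << _U(2 * (k - 1 - j))
        rc |= comp[j : j + n] << _U(2 * j)
    amb = ps.is_ambiguous()
    cum = np.concatenate(([0], np.cumsum(amb)))
    valid = (cum[k:] - cum[:-k]) == 0
    return fwd, rc, valid


def canonical_hashes(ps: PackedSeq, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical (strand-symmetric) hash of every k-mer start.

    Returns (hashes, valid).  Invalid positions hold an arbitrary value and
    must be excluded via the mask.
    """
    fwd, rc, valid = rolling_kmers(ps, k)
    return hash64_array(np.minimum(fwd, rc)), valid


_SENTINEL = np.uint64(0xFFFFFFFFFFFFFFFF)


def sample_minimizers(seq: str | PackedSeq, k: int, w: int) -> list[tuple[int, int]]:
    """Window minimizers over canonical k-mer hashes.

    Each window of ``w`` consecutive k-mers contributes its minimum-hash
    k-mer (leftmost on ties); duplicate selections are collapsed so each
    position appears once.  Expected density on random sequence is 2/(w+1).
    """
    ps = seq if isinstance(seq, PackedSeq) else PackedSeq.from_str(seq)
    hashes, valid = canonical_hashes(ps, k)
    n = hashes.size
    if n == 0:
        return []
    h = np.where(valid, hashes, _SENTINEL)
    if n < w:
        w = n
    windows = np.lib.stride_tricks.sliding_window_view(h, w)
    picks = np.argmin(windows, axis=1) + np.arange(windows.shape[0])
    picks = np.unique(picks)
    picks = picks[valid[picks]]
    return [(int(p), int(hashes[p])) for p in picks]


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (name, sequence) from a (multi-record, wrapped, mixed-case)
    FASTA file."""
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fasta"):
        yield rec.id, str(rec.seq).upper()
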