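"""Synthetic genomes, mutated haplotypes, simulated reads, and truth-based
accuracy evaluation.

The generators emulate the standard read-alignment benchmarking setup:
reads are sampled from a *haplotype* that diverges from the reference by
SNPs and short indels, sequencing errors are added as substitutions, and the
truth interval of every read is expressed in reference coordinates through
an exact liftover map.  A repeat-genome generator concatenates divergent
copies of one unit to probe behaviour on repetitive sequence.

Divergence presets (SNP rate, indel rate): SIM1 (0.001, 0.0001), SIM2
(0.002, 0.0002), SIM3 (0.005, 0.0005), SIM4 (0.01, 0.001) — four increasing
levels, SIM3 being roughly the variation of a human sample against the
reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SIM_PRESETS",
    "SimConfig",
    "TruthRecord",
    "SimulatedRead",
    "simulate_genome",
    "simulate_repeats",
    "mutate_genome",
    "simulate_reads",
    "write_fastq",
    "write_truth",
    "read_truth",
    "evaluate_accuracy",
    "AccuracySummary",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

SIM_PRESETS: dict[str, tuple[float, float]] = {
    "SIM1": (0.001, 0.0001),
    "SIM2": (0.002, 0.0002),
    "SIM3": (0.005, 0.0005),
    "SIM4": (0.01, 0.001),
}

MAX_INDEL_LEN = 20
INDEL_GEOM_P = 0.5  # geometric length distribution, mean 1/p = 2 bp


@dataclass(frozen=True)
class SimConfig:
    read_len: int = 150
    n_reads: int = 1000            # reads (single) or pairs (paired)
    paired: bool = False
    insert_mu: float = 300.0
    insert_sigma: float = 50.0
    error_rate: float = 0.001      # per-base substitution errors
    seed: int = 0                  # mandatory for reproducibility

    def __post_init__(self):
        if not 0 <= self.error_rate <= 1:
            raise ValueError("error rate must be in [0, 1]")


@dataclass(frozen=True)
class TruthRecord:
    read_id: str
    mate: int          # 0 = single-end, 1/2 = mate in a pair
    ref_name: str
    start: int         # reference coordinates, 0-based half-open
    end: int
    strand: str


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    mate: int
    seq: str
    qual: str


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def simulate_genome(length: int, seed: int) -> str:
    """i.i.d. uniform ACGT sequence; deterministic given the seed."""
    if length < 1:
        raise ValueError("genome length must be >= 1")
    return _BASES[_rng(seed).integers(0, 4, size=length)].tobytes().decode()


def simulate_repeats(n_copies: int, unit_len: int, divergence: float, seed: int) -> str:
    """Concatenation of ``n_copies`` independently mutated copies of one
    random unit, each at the given per-base substitution rate."""
    if not 0 <= divergence <= 0.5:
        raise ValueError("divergence must be in [0, 0.5]")
    rng = _rng(seed)
    unit = _BASES[rng.integers(0, 4, size=unit_len)]
    copies = []
    for _ in range(n_copies):
        c = unit.copy()
        hit = np.flatnonzero(rng.random(unit_len) < divergence)
        # substitute with one of the three other bases
        c[hit] = _BASES[(np.searchsorted(_BASES, c[hit]) + rng.integers(1, 4, hit.size)) % 4]
        copies.append(c)
    return np.concatenate(copies).tobytes().decode() if copies else ""


def mutate_genome(
    ref: str, snp_rate: float, indel_rate: float, seed: int
) -> tuple[str, np.ndarray]:
    """Mutated haplotype plus an exact liftover map.

    SNPs always change the base; indel lengths are geometric (p=0.5, capped
    at 20 bp), insertions and deletions equally likely.  The returned int64
    array maps every haplotype position to its reference position, with -1
    marking inserted bases.
    """
    if not (0 <= snp_rate <= 1 and 0 <= indel_rate <= 1):
        raise ValueError("rates must be in [0, 1]")
    rng = _rng(seed)
    L = len(ref)
    codes = np.frombuffer(ref.encode(), dtype=np.uint8).copy()
    u = rng.random(L)
    snp_pos = np.flatnonzero(u < snp_rate)
    indel_pos = np.flatnonzero((u >= snp_rate) & (u < snp_rate + indel_rate))
    # SNPs: shift to one of the three other bases
    idx = np.searchsorted(_BASES, codes[snp_pos])
    codes[snp_pos] = _BASES[(idx + rng.integers(1, 4, snp_pos.size)) % 4]
    hap_parts: list[np.ndarray] = []
    lift_parts: list[np.ndarray] = []
    cur = 0
    for pos in indel_pos:
        pos = int(pos)
        if pos < cur:
            continue  # swallowed by a previous deletion
        hap_parts.append(codes[cur:pos])
        lift_parts.append(np.arange(cur, pos, dtype=np.int64))
        length = int(min(rng.geometric(INDEL_GEOM_P), MAX_INDEL_LEN))
        if rng.random() < 0.5:  # insertion after this reference base
            hap_parts.append(codes[pos : pos + 1])
            lift_parts.append(np.array([pos], dtype=np.int64))
            hap_parts.append(_BASES[rng.integers(0, 4, size=length)])
            lift_parts.append(np.full(length, -1, dtype=np.int64))
            cur = pos + 1
        else:  # deletion of `length` reference bases
            cur = pos + length
    hap_parts.append(codes[cur:L])
    lift_parts.append(np.arange(cur, L, dtype=np.int64))
    hap = np.concatenate(hap_parts)
    lift = np.concatenate(lift_parts)
    return hap.tobytes().decode(), lift


def _truth_interval(lift: np.ndarray, s: int, e: int) -> tuple[int, int]:
    vals = lift[s:e]
    vals = vals[vals >= 0]
    while vals.size == 0:  # read entirely inside an insertion (rare)
        s = max(0, s - 10)
        e = min(lift.size, e + 10)
        vals = lift[s:e]
        vals = vals[vals >= 0]
    return int(vals.min()), int(vals.max()) + 1


def _apply_errors(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return seq
    hit = np.flatnonzero(rng.random(seq.size) < rate)
    if hit.size:
        seq = seq.copy()
        idx = np.searchsorted(_BASES, seq[hit])
        seq[hit] = _BASES[(idx + rng.integers(1, 4, hit.size)) % 4]
    return seq


_RC = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGT", b"TGCA"):
    _RC[_a] = _b


def _rc(arr: np.ndarray) -> np.ndarray:
    return _RC[arr][::-1]


def simulate_reads(
    haplotype: str,
    lift: np.ndarray,
    config: SimConfig,
    ref_name: str = "ref",
) -> tuple[list[SimulatedRead], list[TruthRecord]]:
    """Uniformly sampled reads (or FR pairs with normally distributed insert
    sizes truncated at the read length) with substitution errors; truth
    intervals are reported in reference coordinates via the liftover map."""
    rng = _rng(config.seed)
    hap = np.frombuffer(haplotype.encode(), dtype=np.uint8)
    L = hap.size
    rl = config.read_len
    if rl > L:
        raise ValueError("read length exceeds genome length")
    qual = "I" * rl
    reads: list[SimulatedRead] = []
    truth: list[TruthRecord] = []

    def emit(rid: str, mate: int, s: int, e: int, strand: str) -> None:
        frag = hap[s:e]
        if strand == "-":
            frag = _rc(frag)
        frag = _apply_errors(frag, config.error_rate, rng)
        reads.append(SimulatedRead(rid, mate, frag.tobytes().decode(), qual))
        ts, te = _truth_interval(lift, s, e)
        truth.append(TruthRecord(rid, mate, ref_name, ts, te, strand))

    for i in range(config.n_reads):
        rid = f"r{i}"
        if config.paired:
            t = int(round(rng.normal(config.insert_mu, config.insert_sigma)))
            t = max(rl, min(t, L))
            s = int(rng.integers(0, L - t + 1))
            flip = bool(rng.random() < 0.5)
            if not flip:
                emit(rid, 1, s, s + rl, "+")
                emit(rid, 2, s + t - rl, s + t, "-")
            else:
                emit(rid, 1, s + t - rl, s + t, "-")
                emit(rid, 2, s, s + rl, "+")
        else:
            s = int(rng.integers(0, L - rl + 1))
            strand = "-" if rng.random() < 0.5 else "+"
            emit(rid, 0, s, s + rl, strand)
    return reads, truth


# ---------------------------------------------------------------------------
# file round-trips

def write_fastq(reads: list[SimulatedRead], path: str | Path, mate: int = 0) -> None:
    with open(path, "w") as fh:
        for r in reads:
            if r.mate == mate or mate == 0 and r.mate == 0:
                fh.write(f"@{r.read_id}\n{r.seq}\n+\n{r.qual}\n")


def write_truth(truth: list[TruthRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tmate\tref\tstart\tend\tstrand\n")
        for t in truth:
            fh.write(f"{t.read_id}\t{t.mate}\t{t.ref_name}\t{t.start}\t{t.end}\t{t.strand}\n")


def read_truth(path: str | Path) -> list[TruthRecord]:
    out = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            rid, mate, ref, s, e, strand = line.rstrip("\n").split("\t")
            out.append(TruthRecord(rid, int(mate), ref, int(s), int(e), strand))
    return out


@dataclass
class AccuracySummary:
    n_reads: int
    n_aligned: int
    n_correct: int
    by_mapq: dict[int, tuple[int, int]] = field(default_factory=dict)

    @property
    def percent_aligned(self) -> float:
        return 100.0 * self.n_aligned / self.n_reads if self.n_reads else 0.0

    @property
    def percent_correct(self) -> float:
        """Percent of aligned reads overlapping their true location."""
        return 100.0 * self.n_correct / self.n_aligned if self.n_aligned else 0.0

    def to_tsv(self) -> str:
        lines = [
            "metric\tvalue",
            f"n_reads\t{self.n_reads}",
            f"n_aligned\t{self.n_aligned}",
            f"n_correct\t{self.n_correct}",
            f"percent_aligned\t{self.percent_aligned:.4f}",
            f"percent_correct\t{self.percent_correct:.4f}",
            "mapq\taligned\tcorrect",
        ]
        for q in sorted(self.by_mapq):
            a, c = self.by_mapq[q]
            lines.append(f"{q}\t{a}\t{c}")
        return "\n".join(lines) + "\n"


def evaluate_accuracy(
    sam_path: str | Path, truth: list[TruthRecord], min_overlap: int = 1
) -> AccuracySummary:
    """Compare primary SAM records against the simulation truth.

    A read counts as correct iff it aligned to the truth reference and its
    reported interval overlaps the truth interval by at least
    ``min_overlap`` bp.  Every SAM read id must be present in the truth.
    """
    import pysam

    by_key = {(t.read_id, t.mate): t for t in truth}
    summary = AccuracySummary(n_reads=len(truth), n_aligned=0, n_correct=0)
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            mate = 0 if not rec.is_paired else (1 if rec.is_read1 else 2)
            t = by_key.get((rec.query_name, mate))
            if t is None:
                raise ValueError(f"read {rec.query_name}/{mate} not in truth")
            if rec.is_unmapped:
                continue
            summary.n_aligned += 1
            ok = (
                rec.reference_name == t.ref_name
                and min(rec.reference_end, t.end) - max(rec.reference_start, t.start)
                >= min_overlap
            )
            if ok:
                summary.n_correct += 1
            a, c = summary.by_mapq.get(rec.mapping_quality, (0, 0))
            summary.by_mapq[rec.mapping_quality] = (a + 1, c + (1 if ok else 0))
    return summary
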