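# Methods

This note documents the models and procedures implemented in `randalign`,
the parameter defaults and why they hold, the numerical conventions, and
the limits of what the synthetic-data experiments can show.

## Sequence encoding and hashing

Nucleotides are 2-bit encoded (A=00, C=01, G=10, T=11) with the first base
of a k-mer in the most significant position, so `TCA` = 0b110100 = 52.
Coordinates are 0-based and half-open everywhere; the only conversion to
1-based happens when SAM records are written. k-mers overlapping any
non-ACGT base are skipped and scanning resumes past the ambiguous run, the
standard aligner treatment of N-runs.

Hashing uses the splitmix64 finalizer (xorshift-multiply constants
`0xbf58476d1ce4e5b9`, `0x94d049bb133111eb`), a fixed bijective permutation
of the 64-bit space. Bijectivity matters twice: the mixer itself can never
collide two distinct k-mer encodings, and the test suite verifies the
implementation by inverting it. Canonical hashing takes the numerically
smaller of a k-mer's forward and reverse-complement encodings before
mixing; since the 2-bit order is the lexicographic order, this is the usual
canonical representation.

## Seeding

**Open syncmers (k, s, t).** A k-mer is selected iff the minimum canonical
hash among its k−s+1 constituent s-mers occurs at offset t (1-based; ties
resolve to the smallest offset). Defaults k=20, s=16, t=3. With k−s+1 odd
and t = ⌈(k−s+1)/2⌉ central, selection is strand-symmetric: the same
genomic positions are chosen from either strand, which the test suite
asserts exactly. Expected density is 1/(k−s+1) = 1/5 at the defaults,
matching window minimizers at w=9 (density 2/(w+1)).

**Skewed randstrobe linking.** For the syncmer at index j the candidate
window is the w_min-th through w_max-th following syncmers (count-based),
truncated to candidates whose end stays within `max_seed_len` bases. The
second strobe minimizes B((h(k₁) ⊕ h(k′)) & p-mask) — the popcount of the
masked XOR over the p=8 leftmost bits. Because the value space collapses to
[0, p] and collisions resolve to the leftmost candidate, nearby strobes are
chosen preferentially, which improves mapping of shorter reads. The
unskewed masked-sum rule is provided (`link_randstrobe_sum`) for
comparison only.

**Symmetric seed hash.** A seed stores h′ = ⌊h(k₁)/2⌋ + ⌊h(k₂)/2⌋, which is
symmetric in its arguments and cannot overflow 64 bits. Together with
canonical syncmer hashes this makes a seed hash identical whether the
strobemer is assembled left-to-right or right-to-left, so repeat masking
treats both orientations consistently.

**Read seeds and coordinates.** Syncmers are computed once per read;
forward seeds link them in forward order, reverse-orientation seeds in
reverse order. Reverse-orientation seed coordinates are expressed on the
reverse-complemented read axis. This is a deliberate choice: it makes
matches on either strand collinear with the reference, which the merge
conditions below require (with forward-read coordinates, reverse-strand
chains would have anti-correlated query/reference starts and could never
merge). A consequence worth stating explicitly: linking is directional, so
building an index from a reverse-complemented genome yields per-anchor
pairings that only *frequently* coincide with the forward pairings — the
seed-hash multisets of the two indexes are similar but not identical. The
guaranteed symmetry is at read level: a reverse-complemented read
regenerates exactly the reference seeds of its source locus, including
tie-breaks.

**Fallbacks and caps.** If the candidate window is empty (sequence end,
N-runs, or the span cap), the seed degrades to the single-syncmer fallback,
defined as linking the syncmer with itself (h′(k₁,k₁) = 2·⌊h(k₁)/2⌋), which
keeps reference and query behaviour consistent. Offsets that cannot fit the
8-bit index field (possible only under long-read profiles) are likewise
demoted and counted in a diagnostic. `max_seed_len` defaults to the median
read length minus 50, floored at k+1.

**Read-length profiles.** The (k, s_delta, p, l, u) tuple is selected from
the median length x̃ of the first 500 reads:

| x̃ | k | k−s | p | l | u |
|---|---|-----|---|---|---|
| ≤ 75 | 20 | 4 | 8 | −4 | 2 |
| 75–125 | 20 | 4 | 8 | −2 | 2 |
| 125–175 | 20 | 4 | 8 | 1 | 7 |
| 175–275 | 20 | 4 | 8 | 4 | 13 |
| 275–375 | 22 | 4 | 8 | 2 | 12 |
| > 375 | 23 | 6 | 8 | 2 | 12 |

with w_min = ⌊k/(k−s+1)⌋ + l and w_max = ⌊k/(k−s+1)⌋ + u. The shortest-read
row would give w_min = 0; it is clamped to 1 so the window always starts at
a strictly downstream syncmer.

## Index

Seeds of all references live in one flat vector of (hash, r_s, v) records,
v packing the reference id in the rightmost 24 bits and the second-strobe
offset in the leftmost 8. The vector is sorted by (hash, ref id, r_s) — the
full ordering makes builds byte-reproducible — and a directory maps each
distinct hash to its (offset, count) slice. The abundance cutoff A is the
occurrence count of the distinct hash at descending rank ⌈f·M⌉ (M distinct
hashes, masking fraction f = 0.0002 by default), floored at 2; a lookup
whose count exceeds A reports MASKED. On small genomes where f·M < 1 the
quantile lands on the most abundant hash and nothing is masked, which is
the intended degeneration. Serialization is a versioned magic line, a JSON
header, and the three arrays in npy format; loading verifies the magic and
fails cleanly on truncation.

## Candidate mapping

For each read seed below the cutoff, every reference occurrence becomes a
match; d is the absolute difference between the seed's reference span and
query span. The streaming filter keeps a match iff d ≤ the running minimum
(then updates it) — deliberately order-dependent: prefix-minimum matches
with larger d survive, unlike a two-pass global-minimum filter. Rescue mode
(triggered when >30% of a read's seed instances were masked) sorts seeds by
reference abundance, accepts those below R·A (R=2 by default; an absolute
interpretation of R is available behind `--rescue-absolute`), widens to a
hard cap of 1000 if fewer than 5 qualify, and replays the same streaming
filter; zero matches after rescue means unmapped.

Matches sorted by query start are swept into merged matches. A match m′
joins an open merged match whose last-added match m satisfies: (i) same
reference and orientation; (ii) m.q_s < m′.q_s ≤ m.q_e; (iii) m.r_s <
m′.r_s ≤ m.r_e; (iv) the four strobes are ordered consistently on query and
reference (both staggered or both nested). Query-staggered but
reference-nested configurations — local repeat artifacts — stay separate.
Merged matches close once the sweep passes their rightmost query end;
duplicates are ignored so the output is invariant to repeated matches.

Scoring: S_M = (min{a, b} − |a−b|)·n over query span a, reference span b,
and match count n; MAPQ = 40·(1−S₂/S₁)·min{1, n/10}·ln S₁ from the top two
merged-match scores, floored and clamped to [0, 60] (natural log; a single
candidate sets S₂=0; S₁ ≤ 0 gives 0). Ties in candidate order break by
(reference id, reference start) for determinism.

## Alignment

Candidates are extended best-first, at most 20, stopping at a drop-off of
0.5·S₁, on a perfect match, or after an edit-distance-1 alignment (further
base-level calls cannot beat it; already-computed candidates still
compete). When a merged match spans equally on query and reference the read
is projected onto the reference at r_s − q_s and compared by Hamming
distance (score = matches − 4·mismatches, CIGAR one M-run); if the distance
exceeds 5% of the read, compensating indels may be hiding, so a full local
alignment is also run and the higher score kept. Unequal spans extract the
segment [r_s − q_s − 20, r_e + (|q| − q_e) + 20), clipped to the contig, and
run Smith-Waterman. Local alignment uses Biopython's `PairwiseAligner`
(scores 1, −4, −6, −1; a gap of length l costs 6 + (l−1)); unaligned read
ends become soft clips, CIGARs use M (not =/X), and NM counts mismatches
plus gap bases in the aligned region. The reported score always re-derives
from the emitted CIGAR under the same scheme, which the suite checks
exactly against a textbook three-state DP.

**Paired-end.** The insert-size model N(μ, σ) is estimated once from the
first 500 pairs in which both mates have a strictly unique best merged
match on the same reference in FR orientation; observations outside
median ± 10·MAD are discarded, σ is floored at 1, and fewer than 100 usable
observations fall back to μ=300, σ=100 with a warning. Candidate pairs are
ranked by joint count C_ij = n_i + n_j when proper (same reference, FR,
fragment < μ + 10σ) or by the individual counts otherwise, extended in rank
order, and scored S_ij = SW_i + SW_j + ln N(d_ij; μ, σ) for proper pairs
(d_ij the outer fragment span of the base-level alignments) or
SW_i + SW_j − 10 for split placements (−10 ≈ more than four standard
deviations of insert penalty). The joint MAPQ comes from the top two S_ij
at *distinct* placements — the individually-scored copy of the same two
locations is not a competitor — with n = C of the winner; both mates
receive it. A mate with no merged matches at all is aligned inside a
window μ + 5σ (plus one read length) downstream of its placed partner in
the expected orientation and accepted only at a score of at least half its
length. SAM output carries primary records only, proper-pair/mate flags,
signed TLEN (positive on the leftmost mate), and NM/AS tags; unmapped reads
keep their sequence and quality.

## Synthetic data

`simulate_genome` draws i.i.d. uniform ACGT; `simulate_repeats`
concatenates n copies of one unit, each independently substituted at the
given divergence (50 copies at 10% divergence emulate, at reduced scale, a
repeat genome of ~81–90% pairwise identity). `mutate_genome` applies SNPs
(never identity substitutions) and indels (lengths geometric with p=0.5,
capped at 20 bp; insertions and deletions equally likely) and returns an
exact per-base liftover map, so every read's truth interval is expressed in
reference coordinates. Reads sample uniform start positions and strands;
paired mode draws the fragment length from N(μ, σ) truncated at the read
length and emits FR mates; sequencing errors are uniform substitutions.
Divergence presets SIM1–SIM4 are (SNP, indel) = (0.1%, 0.01%), (0.2%,
0.02%), (0.5%, 0.05%), (1%, 0.1%) — four increasing levels with SIM3 near
the variation of a human sample.

What the generator does *not* emulate: position- and motif-dependent
Illumina error profiles, quality-score structure (qualities are constant),
GC bias, coverage waves, structural variation, and genome-scale repeat
taxonomy. Passing the end-to-end suite therefore demonstrates correctness
of the algorithmic pipeline and calibration on idealized data, not
performance claims on real genomes.

**Correctness criterion.** A read is evaluated as correct iff it aligned to
the truth reference and its reported interval overlaps the truth interval
by at least 1 bp (configurable via `--min-overlap`).

## Problem sizes and determinism

The simulation experiments run at desk scale as the package's own choice:
densities are measured on 1 Mbp sequences (binomial standard error ≈ 0.0004
at density 0.2), the end-to-end paired-end experiment uses a 1 Mbp genome
with 2000 150-nt pairs at the SIM3 preset, and oracle equivalences run on
≤10 kbp instances where brute force is exact. Every generator takes a
mandatory seed; no stage of the aligner itself is stochastic — all ties
break deterministically — so identical inputs and flags produce a
byte-identical SAM body. The `--threads` flag is accepted for interface
compatibility but execution is serial.

## Known limitations

- Seeds use exactly two strobes; more strobes and alternative sampling
  schemes are out of scope.
- The directional-linking asymmetry described under *Read seeds and
  coordinates* means index builds are not invariant to reverse-complementing
  the input FASTA (read mapping is).
- Only primary alignments are emitted; no secondary/supplementary records,
  no base-quality-aware scoring, no BAM/CRAM (pipe through samtools).
- E-hits relatives (E-size, expected hit rate) are not implemented; the
  hard-masked fraction is instance-weighted, which matches the E-hits
  sampling model (the distinct-weighted variant would differ on skewed
  count distributions).
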