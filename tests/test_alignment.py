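import math

import pytest

from randalign.alignment import (
    AlignmentResult,
    InsertSizeModel,
    ScoringParams,
    align_paired,
    align_single,
    cigar_read_len,
    cigar_ref_len,
    estimate_insert_size,
    extend_candidate,
    extract_segment,
    mate_rescue,
    parse_cigar,
    score_pair,
    smith_waterman,
)
from randalign.index import build_index
from randalign.mapping import MergedMatch
from randalign.nucleo import revcomp
from randalign.samio import sam_pair
from randalign.seeding import FORWARD, REVERSE

from .conftest import random_seq
from .oracles import smith_waterman_score


def rescore_cigar(cigar: str, t_begin: int, query: str, target: str,
                  scoring: ScoringParams = ScoringParams()) -> int:
    """Re-derive the alignment score from an emitted CIGAR."""
    qi, ti, score = 0, t_begin, 0
    for op, n in parse_cigar(cigar):
        if op == "S":
            qi += n
        elif op == "M":
            for _ in range(n):
                score += scoring.match if query[qi] == target[ti] else -scoring.mismatch
                qi += 1
                ti += 1
        elif op == "I":
            score -= scoring.gap_open + (n - 1) * scoring.gap_extend
            qi += n
        elif op == "D":
            score -= scoring.gap_open + (n - 1) * scoring.gap_extend
            ti += n
    return score


class TestSmithWaterman:
    def test_matches_textbook_dp_on_mutated_pairs(self, rng):
        for trial in range(15):
            target = random_seq(rng, 200)
            # plant the query inside with mutations
            start = int(rng.integers(0, 50))
            q = list(target[start : start + 120])
            for _ in range(int(rng.integers(0, 6))):
                i = int(rng.integers(0, len(q)))
                op = rng.random()
                if op < 0.5:
                    q[i] = "ACGT"[int(rng.integers(4))]
                elif op < 0.75:
                    q.insert(i, "ACGT"[int(rng.integers(4))])
                else:
                    del q[i]
            query = "".join(q)
            score, cigar, t_beg, _ = smith_waterman(query, target)
            assert score == smith_waterman_score(query, target)
            assert cigar_read_len(cigar) == len(query)
            assert rescore_cigar(cigar, t_beg, query, target) == score

    def test_empty_inputs(self):
        assert smith_waterman("", "ACGT")[1] == "*"
        assert smith_waterman("ACGT", "")[1] == "*"

    def test_gap_cost_convention(self):
        # one 2 nt deletion inside 40 matches: 40 - (6 + 1) = 33
        target = "A" * 20 + "CG" + "T" * 20
        query = "A" * 20 + "T" * 20
        score, cigar, _, nm = smith_waterman(query, target)
        assert score == 33
        assert cigar == "20M2D20M"
        assert nm == 2


@pytest.fixture(scope="module")
def simple_ref():
    import numpy as np

    rng = np.random.default_rng(31)
    return random_seq(rng, 2000)


class TestExtend:
    def mm_for(self, start, length, o=FORWARD, r_id=0):
        return MergedMatch(r_id, o, 20, length - 20, start + 20, start + length - 20, n=3)

    def test_perfect_read(self, simple_ref):
        read = simple_ref[500:650]
        res = extend_candidate(read, simple_ref, self.mm_for(500, 150))
        assert (res.score, res.cigar, res.edit_distance) == (150, "150M", 0)
        assert res.ref_start == 500

    def test_one_substitution_hamming_path(self, simple_ref):
        read = list(simple_ref[500:650])
        read[75] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[75]]
        res = extend_candidate("".join(read), simple_ref, self.mm_for(500, 150))
        assert res.score == 149 - 4  # 149 matches - one mismatch
        assert res.cigar == "150M"
        assert res.edit_distance == 1

    def test_two_nt_deletion_sw_path(self, simple_ref):
        read = simple_ref[500:575] + simple_ref[577:652]
        mm = MergedMatch(0, FORWARD, 10, 60, 510, 560, n=2)
        res = extend_candidate(read, simple_ref, mm)
        assert res.edit_distance == 2
        assert "D" in res.cigar
        assert res.score == smith_waterman_score(read, simple_ref[480:680])

    def test_reverse_candidate(self, simple_ref):
        read = revcomp(simple_ref[800:950])
        # coordinates of the merged match are on the rc-read axis
        mm = MergedMatch(0, REVERSE, 20, 130, 820, 930, n=3)
        res = extend_candidate(read, simple_ref, mm)
        assert (res.ref_start, res.score, res.strand) == (800, 150, REVERSE)

    def test_hamming_equals_sw_when_indel_free(self, simple_ref, rng):
        for _ in range(10):
            start = int(rng.integers(0, 1800))
            read = list(simple_ref[start : start + 150])
            for i in map(int, rng.integers(0, 150, size=3)):
                read[i] = "ACGT"[int(rng.integers(4))]
            read = "".join(read)
            mm = self.mm_for(start, 150)
            res = extend_candidate(read, simple_ref, mm)
            sw = smith_waterman_score(read, simple_ref[max(0, start - 20) : start + 170])
            if res.cigar == "150M":
                assert res.score >= sw or res.edit_distance <= 0.05 * 150


class TestSegment:
    def test_clipping_at_reference_start(self):
        mm = MergedMatch(0, FORWARD, 5, 45, 5, 45, n=1)
        seg, start = extract_segment(mm, 50, "A" * 300)
        assert start == 0  # 5 - 5 - pad clips to zero

    def test_contains_true_interval(self, genome100k, profile150):
        from randalign.mapping import candidate_regions

        ix = build_index([("chr1", genome100k)], profile150)
        read = genome100k[12_345:12_495]
        cands, _ = candidate_regions(read, ix)
        seg, start = extract_segment(cands[0], 150, genome100k)
        assert start <= 12_345 and start + len(seg) >= 12_495

    def test_read_over_contig_end_softclips(self, genome100k, index100k):
        read = genome100k[-100:] + random_seq_tail()
        res = align_single(read, index100k)
        assert res.is_aligned
        assert res.cigar.endswith("S")
        assert cigar_read_len(res.cigar) == len(read)


def random_seq_tail():
    import numpy as np

    rng = np.random.default_rng(77)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=50))


class TestAlignSingle:
    def test_error_free_unique(self, genome100k, index100k):
        res = align_single(genome100k[70_000:70_150], index100k)
        assert res.is_aligned
        assert (res.ref_start, res.mapq, res.edit_distance) == (70_000, 60, 0)

    def test_exact_repeat_mapq_zero(self, profile150, rng):
        unit = random_seq(rng, 3000)
        bg1, bg2 = random_seq(rng, 5000), random_seq(rng, 5000)
        ix = build_index([("c1", bg1 + unit), ("c2", bg2 + unit)], profile150)
        res = align_single(unit[1000:1150], ix)
        assert res.is_aligned and res.mapq == 0

    def test_no_candidates_unmapped(self, index100k):
        res = align_single("N" * 150, index100k)
        assert not res.is_aligned

    def test_cigar_consumes_read(self, genome100k, index100k, rng):
        for _ in range(10):
            start = int(rng.integers(0, 99_000))
            read = list(genome100k[start : start + 150])
            for i in map(int, rng.integers(0, 150, size=2)):
                read[i] = "ACGT"[int(rng.integers(4))]
            res = align_single("".join(read), index100k)
            if res.is_aligned:
                assert cigar_read_len(res.cigar) == 150


class TestInsertModel:
    def test_parameter_recovery(self, rng):
        obs = list(rng.normal(350, 40, size=500))
        m = estimate_insert_size(obs)
        assert abs(m.mu - 350) / 350 < 0.05
        assert abs(m.sigma - 40) / 40 < 0.15

    def test_too_few_observations_fallback(self):
        m = estimate_insert_size([300.0] * 50)
        assert (m.mu, m.sigma, m.n_observations) == (300.0, 100.0, 0)

    def test_constant_insert_sigma_floor(self):
        m = estimate_insert_size([300.0] * 200)
        assert m.mu == 300.0 and m.sigma == 1.0

    def test_outlier_trimming(self, rng):
        obs = list(rng.normal(350, 40, size=490)) + [50_000.0] * 10
        m = estimate_insert_size(obs)
        assert abs(m.mu - 350) / 350 < 0.05


class TestPairScore:
    model = InsertSizeModel(mu=300, sigma=50, n_observations=500)

    def mm(self, r_id, o, r_s, r_e, n=5):
        return MergedMatch(r_id, o, 0, 100, r_s, r_e, n=n)

    def test_different_chromosomes_individual(self):
        ps = score_pair(self.mm(0, FORWARD, 0, 100), self.mm(1, REVERSE, 0, 100), self.model)
        assert not ps.proper
        from randalign.alignment import pair_alignment_score

        assert pair_alignment_score(150, 150, self.model, None) == 290

    def test_proper_pair_at_mode(self):
        ps = score_pair(
            self.mm(0, FORWARD, 1000, 1100), self.mm(0, REVERSE, 1200, 1300), self.model
        )
        assert ps.proper and ps.d == 300
        from randalign.alignment import pair_alignment_score

        s = pair_alignment_score(150, 150, self.model, ps.d)
        assert s == pytest.approx(300 - math.log(50 * math.sqrt(2 * math.pi)))

    def test_distance_boundary(self):
        far = self.mm(0, REVERSE, 1000 + 300 + 11 * 50, 1100 + 300 + 11 * 50)
        ps = score_pair(self.mm(0, FORWARD, 1000, 1100), far, self.model)
        assert not ps.proper

    def test_predicate_symmetric(self):
        a = self.mm(0, FORWARD, 1000, 1100)
        b = self.mm(0, REVERSE, 1200, 1300)
        assert score_pair(a, b, self.model).proper == score_pair(b, a, self.model).proper


class TestMateRescue:
    model = InsertSizeModel(mu=300, sigma=50, n_observations=500)

    def test_error_free_mate_recovered(self, genome100k, index100k):
        placed = AlignmentResult(
            is_aligned=True, r_id=0, ref_start=40_000, strand=FORWARD,
            cigar="150M", score=150, mapq=60,
        )
        mate = revcomp(genome100k[40_250:40_400])
        res = mate_rescue(placed, mate, self.model, index100k)
        assert res.is_aligned and res.rescued
        assert res.ref_start == 40_250
        assert res.score == 150
        assert res.strand == REVERSE

    def test_empty_window_unmapped(self, genome100k, index100k):
        placed = AlignmentResult(
            is_aligned=True, r_id=0, ref_start=0, strand=REVERSE, cigar="1M", score=1
        )
        res = mate_rescue(placed, "ACGT" * 40, self.model, index100k)
        assert not res.is_aligned

    def test_junk_mate_rejected(self, index100k):
        placed = AlignmentResult(
            is_aligned=True, r_id=0, ref_start=50_000, strand=FORWARD,
            cigar="150M", score=150,
        )
        res = mate_rescue(placed, "ACGTACGTAC" * 15, self.model, index100k)
        # a random mate may align weakly but must not pass the score floor
        assert not res.is_aligned or res.score >= 75


class TestAlignPaired:
    model = InsertSizeModel(mu=300, sigma=50, n_observations=500)

    def test_error_free_proper_pair(self, genome100k, index100k):
        r1 = genome100k[20_000:20_150]
        r2 = revcomp(genome100k[20_150:20_300])
        a1, a2 = align_paired(r1, r2, index100k, self.model)
        assert a1.ref_start == 20_000 and a2.ref_start == 20_150
        assert (a1.strand, a2.strand) == (FORWARD, REVERSE)
        l1, l2 = sam_pair("p", a1, a2, index100k, r1, "I" * 150, r2, "I" * 150, self.model)
        f1 = l1.split("\t")
        assert int(f1[1]) & 0x2  # proper pair
        assert abs(int(f1[8])) == 300  # |TLEN| == simulated insert

    def test_pair_term_disambiguates_repeat(self, profile150, rng):
        # a two-copy repeat: the repeat mate alone is ambiguous (MAPQ 0),
        # but its unique mate pins the pair to the first copy
        unit = random_seq(rng, 1500)
        between = random_seq(rng, 3000)
        genome = unit + random_seq(rng, 400) + between + unit + random_seq(rng, 4000)
        ix = build_index([("chr", genome)], profile150)
        repeat_read = unit[200:350]
        unique_start = 1500 + 100
        mate = revcomp(genome[unique_start : unique_start + 150])
        solo = align_single(repeat_read, ix)
        assert solo.mapq == 0  # ambiguous alone
        a1, a2 = align_paired(repeat_read, mate, ix, self.model)
        assert a1.is_aligned and a1.ref_start == 200  # first copy chosen
        assert a2.ref_start == unique_start

    def test_both_seedless_unmapped(self, index100k):
        a1, a2 = align_paired("N" * 150, "N" * 150, index100k, self.model)
        assert not a1.is_aligned and not a2.is_aligned

    def test_one_seedless_mate_rescued(self, genome100k, index100k):
        r1 = genome100k[33_000:33_150]
        a1, a2 = align_paired(r1, "N" * 150, index100k, self.model)
        assert a1.is_aligned
        assert not a2.is_aligned  # an all-N mate cannot be base-aligned

    def test_cigar_bookkeeping(self, genome100k, index100k):
        r1 = genome100k[44_000:44_150]
        r2 = revcomp(genome100k[44_200:44_350])
        a1, a2 = align_paired(r1, r2, index100k, self.model)
        for a in (a1, a2):
            assert cigar_read_len(a.cigar) == 150
            assert cigar_ref_len(a.cigar) > 0
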