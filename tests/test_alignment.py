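import math

import numpy as np
import pytest

from circaxis.alignment import (
    DEFAULT_PROFILE,
    DEFAULT_SCORING,
    AlignmentHit,
    ReferenceIndex,
    ScoringScheme,
    bitscore,
    local_align,
    search_reference,
    smith_waterman,
)
from circaxis.external import (
    parse_blast_tab,
    parse_miranda,
    parse_psl,
    read_hits_tsv,
    write_hits_tsv,
)
from circaxis.reference import GenomeRef, reverse_complement

rng = np.random.default_rng(20240915)
_BASES = np.array(list("ACGT"))


def rand_seq(n):
    return "".join(rng.choice(_BASES, size=n))


def seedless_pair(n=200, k=11):
    """Random pair sharing no k-mer (verified, redrawn otherwise)."""
    while True:
        a, b = rand_seq(n), rand_seq(n)
        akmers = {a[i : i + k] for i in range(n - k + 1)}
        if all(b[i : i + k] not in akmers for i in range(n - k + 1)):
            return a, b


class TestLocalAlign:
    def test_self_alignment_full_identity(self):
        q = rand_seq(50)
        hits = local_align(q, q)
        assert hits[0].identity == 1.0
        assert hits[0].query_span == (1, 50) and hits[0].raw_score == 100

    def test_no_shared_seed_no_hits(self):
        a, b = seedless_pair()
        assert local_align(a, b) == []

    def test_single_mismatch(self):
        q = rand_seq(60)
        t = q[:30] + ("A" if q[30] != "A" else "C") + q[31:]
        best = max(local_align(q, t), key=lambda h: h.raw_score)
        assert best.matches == 59 and best.mismatches <= 1

    def test_query_shorter_than_seed(self):
        assert local_align("ACGTACGT", rand_seq(100)) == []

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            local_align("", "ACGT")

    def test_n_never_matches(self):
        q = "N" * 30
        assert local_align(q, q, seed_length=7) == []

    def test_two_separate_planted_copies_give_two_hits(self):
        a, b = seedless_pair(400)
        s1, s2 = rand_seq(40), rand_seq(40)
        q = a[:50] + s1 + a[90:250] + s2 + a[290:]
        t = b[:120] + s2 + b[160:300] + s1 + b[340:]
        hits = [h for h in local_align(q, t) if h.raw_score >= 80]
        assert len(hits) == 2


class TestSmithWatermanOracle:
    """Seed-and-extend must recover the full-matrix optimum (spot checks;
    the exhaustive sweep lives in the acceptance suite)."""

    def test_matches_biotite_on_mutated_copies(self):
        import biotite.sequence as bseq
        import biotite.sequence.align as balign

        mat = balign.SubstitutionMatrix(
            bseq.NucleotideSequence.alphabet_unamb,
            bseq.NucleotideSequence.alphabet_unamb,
            np.array(
                [[2, -3, -3, -3], [-3, 2, -3, -3], [-3, -3, 2, -3], [-3, -3, -3, 2]],
                dtype=np.int32,
            ),
        )
        for _ in range(25):
            q = rand_seq(int(rng.integers(40, 180)))
            t = list(rand_seq(int(rng.integers(40, 180))))
            w = int(rng.integers(12, min(len(q), len(t))))
            qs = int(rng.integers(0, len(q) - w + 1))
            ts = int(rng.integers(0, len(t) - w + 1))
            t[ts : ts + w] = q[qs : qs + w]
            t = "".join(t)
            mine = max((h.raw_score for h in local_align(q, t)), default=0)
            ref = balign.align_optimal(
                bseq.NucleotideSequence(q), bseq.NucleotideSequence(t),
                mat, gap_penalty=(-5, -2), local=True, max_number=1,
            )[0].score
            assert mine == ref

    def test_affine_gap_convention(self):
        # a 2-nt target insertion between two perfect 20-mers:
        # 40 matches (80) minus open(5) + extend(2) = 73
        left, right = rand_seq(20), rand_seq(20)
        q = left + right
        t = left + "AT" + right
        best = smith_waterman(q, t)
        assert best.raw_score == 80 - 5 - 2
        assert best.gap_bases == 2


class TestBitscore:
    def test_closed_form_values(self):
        assert bitscore(0) == pytest.approx(-math.log(0.41) / math.log(2), abs=1e-3)
        assert bitscore(120) == pytest.approx((0.625 * 120 - math.log(0.41)) / math.log(2), abs=1e-3)
        assert bitscore(120) == pytest.approx(109.5, abs=0.1)

    def test_monotone(self):
        scores = [0, 10, 55, 120, 300]
        bits = [bitscore(s) for s in scores]
        assert bits == sorted(bits)

    def test_invalid_scoring_rejected(self):
        with pytest.raises(ValueError):
            ScoringScheme(match=0)
        with pytest.raises(ValueError):
            ScoringScheme(k=-1)


class TestSearchReference:
    def test_strand_symmetry(self):
        chrom = rand_seq(3000)
        genome = GenomeRef({"chr1": chrom})
        ref = ReferenceIndex(genome)
        q = chrom[1000:1150]
        fwd = search_reference(q, ref, DEFAULT_PROFILE)
        rev = search_reference(reverse_complement(q), ref, DEFAULT_PROFILE)
        key = lambda hs: sorted((h.target_id, h.target_span, h.raw_score, h.split) for h in hs)
        assert key(fwd) == key(rev)
        strands = {h.strand for h in fwd if not h.split} ^ {h.strand for h in rev if not h.split}
        assert strands in (set(), {"+", "-"})

    def test_unique_sequence_single_locus(self):
        chrom = rand_seq(3000)
        genome = GenomeRef({"chr1": chrom})
        ref = ReferenceIndex(genome)
        hits = search_reference(chrom[500:700], ref, DEFAULT_PROFILE)
        strong = [h for h in hits if h.raw_score >= 100]
        assert len(strong) == 1
        assert strong[0].target_span == (501, 700)


class TestExternalParsers:
    PSL_LINE = (
        "190\t10\t0\t0\t0\t0\t0\t0\t+\tq1\t200\t0\t200\tchr9\t5000\t1000\t1200\t1\t200,\t0,\t1000,\n"
    )
    PSL_SPLIT = (
        "200\t0\t0\t0\t0\t0\t1\t1000\t+\tq2\t200\t0\t200\tchr9\t9000\t1000\t2200\t2\t100,100,\t0,100,\t1000,2100,\n"
    )

    def test_psl_single_block(self, tmp_path):
        p = tmp_path / "x.psl"
        p.write_text("psLayout version 3\n\nmatch\tmis\n-------\n" + self.PSL_LINE)
        (hit,) = parse_psl(p)
        assert hit.matches == 190 and hit.mismatches == 10
        assert hit.target_span == (1001, 1200)
        assert not hit.split

    def test_psl_two_block_split(self, tmp_path):
        p = tmp_path / "x.psl"
        p.write_text(self.PSL_SPLIT)
        (hit,) = parse_psl(p)
        assert hit.split and hit.raw_score == 199

    def test_psl_malformed_rejected(self, tmp_path):
        p = tmp_path / "x.psl"
        p.write_text("1\t2\t3\n")
        with pytest.raises(ValueError):
            parse_psl(p)

    def test_blast_tab_fields(self, tmp_path):
        p = tmp_path / "x.tsv"
        p.write_text("q1\tchr2\t85.00\t60\t9\t0\t1\t60\t500\t441\t1e-20\t110\n")
        (hit,) = parse_blast_tab(p)
        assert hit.strand == "-" and hit.target_span == (441, 500)
        assert hit.matches == 51 and hit.mismatches == 9
        assert bitscore(hit.raw_score) == pytest.approx(110, abs=1e-6)

    def test_blast_tab_error_carries_line_number(self, tmp_path):
        p = tmp_path / "x.tsv"
        p.write_text("q1\tchr2\tnot_a_number\t60\t9\t0\t1\t60\t500\t441\t1e-20\t110\n")
        with pytest.raises(ValueError, match=":1"):
            parse_blast_tab(p)

    def test_miranda_hits_and_empty(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text(
            "Performing Scan: miR-1 vs circA\n"
            ">miR-1\tcircA\t160.00\t-25.00\t2 21\t50 72\t19\t85.00%\t90.00%\n"
            ">>miR-1\tcircA\t160.00\t-25.00\t...\n"
        )
        (site,) = parse_miranda(p)
        assert site.mirna_id == "miR-1" and site.score == 160.0 and site.energy == -25.0
        assert (site.start, site.end) == (50, 72)
        empty = tmp_path / "e.txt"
        empty.write_text("")
        assert parse_miranda(empty) == []

    def test_hits_tsv_round_trip(self, tmp_path):
        hits = [
            AlignmentHit("q", "chr1", "genome", "-", (3, 50), (100, 148), 40, 6, 2, 62.0, True),
            AlignmentHit("q", "t1", "transcript", "+", (1, 20), (5, 24), 20, 0, 0, 40.0),
        ]
        p = tmp_path / "hits.tsv"
        write_hits_tsv(hits, p)
        assert read_hits_tsv(p) == hits
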