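import numpy as np
import pytest

from circaxis.junctions import CircleSequence
from circaxis.reference import reverse_complement
from circaxis.targeting import (
    MiRNASite,
    annotate_clip_support,
    circularize_for_scan,
    collapse_to_interactions,
    duplex_score,
    filter_sites,
    scan_sites_builtin,
    site_genomic_intervals,
)

rng = np.random.default_rng(11)


def rand_seq(n):
    return "".join(rng.choice(list("ACGT"), size=n))


MIRNA = "TAGCTTATCAGACTGATGTTGA"  # 22 nt


def _circle(seq, event_id="e", spans=None, strand="+", chrom="chr1"):
    spans = spans or ((1001, 1000 + len(seq)),)
    return CircleSequence(event_id, "tx", chrom, strand, spans, seq)


def _plant(seq, mirna, pos):
    """Write the site (revcomp of the miRNA) at 1-based circle position."""
    site = reverse_complement(mirna)
    out = list(seq)
    for i, ch in enumerate(site):
        out[(pos - 1 + i) % len(seq)] = ch
    return "".join(out)


def _clean_background(n, mirna):
    """Background without the miRNA's seed reverse complement."""
    from circaxis.targeting import SEED_END, SEED_START

    seed_rc = reverse_complement(mirna[SEED_START - 1 : SEED_END])
    while True:
        s = rand_seq(n)
        if seed_rc not in s + s[:30]:
            return s


class TestCircularize:
    def test_extension_and_length(self):
        ext, L = circularize_for_scan("A" * 300, overhang=30)
        assert L == 300 and len(ext) == 330

    def test_short_circle_extension_capped(self):
        ext, L = circularize_for_scan("ACGT" * 5, overhang=100)
        assert len(ext) == 40


class TestDuplexScore:
    def test_perfect_22mer(self):
        score, energy = duplex_score(MIRNA, reverse_complement(MIRNA))
        # 7 seed pairs doubled + 15 plain pairs = 29 weighted
        assert score == pytest.approx(174.0)
        assert energy == pytest.approx(-34.8)

    def test_gu_wobble_counts_half(self):
        site = list(reverse_complement(MIRNA))
        # make the pairing at miRNA position 11 (non-seed, a G) a G:U wobble
        pos = 11
        idx = len(MIRNA) - pos
        m_base = MIRNA[pos - 1]
        site[idx] = {"G": "T", "T": "G"}.get(m_base, "X")
        assert site[idx] != "X"
        score, _ = duplex_score(MIRNA, "".join(site))
        assert score == pytest.approx(174.0 - 6.0 * 0.5)

    def test_mismatch_scores_zero(self):
        site = list(reverse_complement(MIRNA))
        site[0] = MIRNA[-1]  # self-base never pairs
        score, _ = duplex_score(MIRNA, "".join(site))
        assert score == pytest.approx(174.0 - 6.0)


class TestScanner:
    def test_planted_perfect_site_found_at_position(self):
        seq = _plant(_clean_background(400, MIRNA), MIRNA, 50)
        circle = _circle(seq)
        sites = scan_sites_builtin(circle, "miR-x", MIRNA)
        assert len(sites) == 1
        s = sites[0]
        assert s.start == 50 and not s.spans_junction
        assert s.score == pytest.approx(174.0) and s.energy < -20

    def test_junction_spanning_site(self):
        L = 400
        pos = L - 10
        seq = _plant(_clean_background(L, MIRNA), MIRNA, pos)
        sites = scan_sites_builtin(_circle(seq), "miR-x", MIRNA)
        assert len(sites) == 1
        assert sites[0].spans_junction
        assert sites[0].start == pos and sites[0].end == (pos + len(MIRNA) - 2) % L + 1

    def test_clean_circle_reports_nothing(self):
        assert scan_sites_builtin(_circle(_clean_background(400, MIRNA)), "m", MIRNA) == []

    def test_rotation_invariance(self):
        seq = _plant(_clean_background(400, MIRNA), MIRNA, 50)
        base = scan_sites_builtin(_circle(seq), "m", MIRNA)
        for shift in (37, 200, 399):
            rotated = seq[shift:] + seq[:shift]
            got = scan_sites_builtin(_circle(rotated), "m", MIRNA)
            assert len(got) == len(base)
            assert [s.score for s in got] == [s.score for s in base]

    def test_seed_only_site_scores_below_perfect(self):
        seq = _clean_background(400, MIRNA)
        M = len(MIRNA)
        site = list(reverse_complement(MIRNA))
        for idx in range(M):
            mirna_pos = M - idx
            if not (2 <= mirna_pos <= 8):
                site[idx] = MIRNA[mirna_pos - 1]
        out = list(seq)
        out[49 : 49 + M] = site
        sites = scan_sites_builtin(_circle("".join(out)), "m", MIRNA)
        assert len(sites) == 1
        assert sites[0].score < 174.0
        assert filter_sites(sites) == []


class TestFilter:
    def _site(self, score, energy):
        return MiRNASite("e", "m", 1, 22, score, energy, False)

    def test_strictness(self):
        assert filter_sites([self._site(155.0, -25.0)]) == []
        assert filter_sites([self._site(160.0, -20.0)]) == []
        assert filter_sites([self._site(160.0, -19.0)]) == []
        kept = filter_sites([self._site(160.0, -25.0)])
        assert len(kept) == 1


class TestClipSupport:
    def test_overlap_marks_supported(self):
        circle = _circle("A" * 200, spans=((1001, 1200),))
        site = MiRNASite("e", "m", 50, 71, 170, -30, False)
        regions = [("chr1", 1060, 1065, "+")]
        (out,) = annotate_clip_support([site], regions, circle)
        assert out.clip_supported

    def test_no_regions_all_false(self):
        circle = _circle("A" * 200)
        site = MiRNASite("e", "m", 50, 71, 170, -30, False)
        (out,) = annotate_clip_support([site], [], circle)
        assert not out.clip_supported

    def test_projection_across_exons(self):
        # two exons 100 nt each; site 95..110 crosses the junction between them
        circle = _circle("A" * 200, spans=((1001, 1100), (2001, 2100)))
        site = MiRNASite("e", "m", 95, 110, 170, -30, False)
        ivs = site_genomic_intervals(circle, site)
        assert ivs == [(1095, 1100), (2001, 2010)]
        # clip region only on the second exon still supports the site
        (out,) = annotate_clip_support([site], [("chr1", 2005, 2006, "+")], circle)
        assert out.clip_supported

    def test_minus_strand_projection(self):
        circle = _circle("A" * 200, spans=((1001, 1200),), strand="-")
        site = MiRNASite("e", "m", 1, 10, 170, -30, False)
        # circle position 1 is the exon's genomic end on '-'
        assert site_genomic_intervals(circle, site) == [(1191, 1200)]


class TestCollapse:
    def test_grouping(self):
        sites = [
            MiRNASite("e1", "miR-1", 10, 31, 160, -25, False),
            MiRNASite("e1", "miR-1", 60, 81, 170, -30, True, clip_supported=True),
            MiRNASite("e1", "miR-1", 120, 141, 165, -27, False),
            MiRNASite("e1", "miR-2", 5, 26, 180, -33, False),
        ]
        out = collapse_to_interactions(sites)
        assert len(out) == 2
        one = next(i for i in out if i.mirna_id == "miR-1")
        assert one.n_sites == 3 and one.max_score == 170
        assert one.any_spans_junction and one.clip_supported

    def test_empty(self):
        assert collapse_to_interactions([]) == []


class TestExternalEquivalence:
    def test_miranda_parse_filter_collapse(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text(
            ">miR-1\te1\t160.00\t-25.00\t2 21\t50 71\t19\t85%\t90%\n"
            ">miR-1\te1\t150.00\t-25.00\t2 21\t90 111\t19\t85%\t90%\n"  # fails score
            ">miR-2\te1\t170.00\t-18.00\t2 21\t10 31\t19\t85%\t90%\n"  # fails energy
            ">miR-2\te2\t180.00\t-30.00\t2 21\t390 11\t19\t85%\t90%\n"  # wraps
        )
        from circaxis.external import parse_miranda

        sites = filter_sites(parse_miranda(p))
        out = collapse_to_interactions(sites)
        assert [(i.event_id, i.mirna_id, i.n_sites) for i in out] == [
            ("e1", "miR-1", 1),
            ("e2", "miR-2", 1),
        ]
        assert out[1].any_spans_junction


class TestOnFixture:
    """Planted miRNA-site truth on the study fixture."""

    def test_interactions_match_plants(self, fixture_obj, net, truth):
        got = {(i.event_id, i.mirna_id): i for i in net.interactions}
        e10 = fixture_obj.circs[10].event_id
        e11 = fixture_obj.circs[11].event_id
        e13 = fixture_obj.circs[13].event_id
        assert got[(e10, "miR-1")].clip_supported
        assert got[(e11, "miR-2")].any_spans_junction
        assert got[(e13, "miR-1")].n_sites == 2
        # the seed-only plant never passes the score filter
        e12 = fixture_obj.circs[12].event_id
        assert (e12, "miR-3") not in got
        assert len(got) == 3
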