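"""miRNA binding-site prediction on circle sequences.

The built-in scanner finds candidate sites by a perfect Watson-Crick match
to the miRNA seed (positions 2-8) and scores the full duplex with a
5'-weighted complementarity sum: seed pairs count double, G:U wobbles count
half.  Score and free-energy estimate are linear in that weighted sum,
calibrated so a perfect ~22-nt duplex scores ~174 with energy ~ -35
kcal/mol; the conventional retention thresholds (score > 155, energy < -20)
then separate perfect/near-perfect sites from seed-only matches.  Sites
spanning the back-splice junction are found by scanning a circularly
extended sequence.

An external predictor's text output can be substituted for the built-in
scanner via :func:`circaxis.external.parse_miranda`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from intervaltree import IntervalTree

from .junctions import CircleSequence
from .reference import reverse_complement

SCORE_THRESHOLD = 155.0
ENERGY_THRESHOLD = -20.0
SCORE_PER_WEIGHT = 6.0
ENERGY_PER_WEIGHT = -1.2
SEED_START, SEED_END = 2, 8  # miRNA positions, 1-based inclusive
DEFAULT_OVERHANG = 25


@dataclass(frozen=True)
class MiRNASite:
    """One predicted miRNA binding site on a circle sequence.

    ``start``/``end`` are 1-based circle positions; a junction-spanning site
    wraps, so its start is greater than its end.
    """

    event_id: str
    mirna_id: str
    start: int
    end: int
    score: float
    energy: float
    spans_junction: bool
    clip_supported: bool = False


@dataclass(frozen=True)
class CircMiInteraction:
    event_id: str
    mirna_id: str
    n_sites: int
    max_score: float
    any_spans_junction: bool
    clip_supported: bool


def circularize_for_scan(circle_seq: str, overhang: int = DEFAULT_OVERHANG) -> tuple[str, int]:
    """Append the first min(overhang, L) nt of the circle to its end.

    Returns the extended sequence and L; extended positions fold back to
    circle positions modulo L.
    """
    L = len(circle_seq)
    if L < 1:
        raise ValueError("empty circle sequence")
    return circle_seq + circle_seq[: min(overhang, L)], L


def _pair_weight(m_base: str, t_base: str) -> float:
    if t_base == reverse_complement(m_base) and m_base != "N":
        return 1.0
    if (m_base, t_base) in (("G", "T"), ("T", "G")):
        return 0.5
    return 0.0


def duplex_score(mirna: str, site: str) -> tuple[float, float]:
    """Score a miRNA against an equal-length target site (5'->3' both).

    The miRNA pairs antiparallel to the site, so miRNA position ``p``
    (1-based from the 5' end) faces site position ``len(site) - p + 1``.
    Returns (pairing score, energy estimate).
    """
    if len(mirna) != len(site):
        raise ValueError("duplex requires equal lengths")
    M = len(mirna)
    weighted = 0.0
    for i, t_base in enumerate(site):
        mirna_pos = M - i  # 1-based position from miRNA 5' end
        w = _pair_weight(mirna[mirna_pos - 1], t_base)
        if SEED_START <= mirna_pos <= SEED_END:
            w *= 2.0
        weighted += w
    return SCORE_PER_WEIGHT * weighted, ENERGY_PER_WEIGHT * weighted


def scan_sites_builtin(
    circle: CircleSequence,
    mirna_id: str,
    mirna_seq: str,
    overhang: int = DEFAULT_OVERHANG,
) -> list[MiRNASite]:
    """All candidate binding sites of one miRNA on one circle (unfiltered).

    Candidates are anchored at perfect Watson-Crick seed matches; sites
    falling wholly inside the circular extension are duplicates of sites at
    the sequence start and are dropped.  Overlapping candidates keep the
    higher-scoring site.
    """
    M = len(mirna_seq)
    if M < 15:
        raise ValueError(f"miRNA {mirna_id!r} shorter than 15 nt")
    ext, L = circularize_for_scan(circle.sequence, max(overhang, M))
    seed_rc = reverse_complement(mirna_seq[SEED_START - 1 : SEED_END])
    sites: list[MiRNASite] = []
    pos = ext.find(seed_rc)
    while pos != -1:
        start0 = pos - (M - SEED_END)  # 0-based site start on ext
        end0 = start0 + M - 1
        if 0 <= start0 < L and end0 < len(ext):
            score, energy = duplex_score(mirna_seq, ext[start0 : end0 + 1])
            spans = end0 >= L
            sites.append(
                MiRNASite(
                    event_id=circle.event_id,
                    mirna_id=mirna_id,
                    start=start0 % L + 1,
                    end=end0 % L + 1,
                    score=score,
                    energy=energy,
                    spans_junction=spans,
                )
            )
        pos = ext.find(seed_rc, pos + 1)
    # resolve overlaps: keep the higher score (ties: leftmost)
    sites.sort(key=lambda s: (-s.score, s.start))
    kept: list[MiRNASite] = []
    occupied: list[tuple[int, int]] = []

    def _intervals(s: MiRNASite) -> list[tuple[int, int]]:
        if s.start <= s.end:
            return [(s.start, s.end)]
        return [(s.start, L), (1, s.end)]

    for s in sites:
        ivs = _intervals(s)
        if any(a <= d and c <= b for a, b in ivs for c, d in occupied):
            continue
        occupied.extend(ivs)
        kept.append(s)
    kept.sort(key=lambda s: (s.start, s.end))
    return kept


def filter_sites(
    sites: list[MiRNASite],
    score_threshold: float = SCORE_THRESHOLD,
    energy_threshold: float = ENERGY_THRESHOLD,
) -> list[MiRNASite]:
    """Keep sites with score strictly above and energy strictly below cutoffs."""
    return [s for s in sites if s.score > score_threshold and s.energy < energy_threshold]


# ---------------------------------------------------------------------------
# Genomic projection and CLIP support


def circle_position_to_genomic(circle: CircleSequence, pos: int) -> int:
    """Map a 1-based circle position (transcription orientation) to genome."""
    if not 1 <= pos <= len(circle):
        raise ValueError(f"position {pos} outside circle of length {len(circle)}")
    if circle.strand == "+":
        remaining = pos
        for s, e in circle.exon_spans:
            width = e - s + 1
            if remaining <= width:
                return s + remaining - 1
            remaining -= width
    else:
        remaining = pos
        for s, e in reversed(circle.exon_spans):
            width = e - s + 1
            if remaining <= width:
                return e - remaining + 1
            remaining -= width
    raise AssertionError("unreachable")


def site_genomic_intervals(circle: CircleSequence, site: MiRNASite) -> list[tuple[int, int]]:
    """Genomic 1-based intervals covered by a site (split at exon joins)."""
    if site.start <= site.end:
        positions = range(site.start, site.end + 1)
    else:  # wraps the junction
        positions = list(range(site.start, len(circle) + 1)) + list(range(1, site.end + 1))
    coords = sorted(circle_position_to_genomic(circle, p) for p in positions)
    intervals: list[list[int]] = []
    for c in coords:
        if intervals and c == intervals[-1][1] + 1:
            intervals[-1][1] = c
        else:
            intervals.append([c, c])
    return [(a, b) for a, b in intervals]


def load_clip_regions(path) -> list[tuple[str, int, int, str]]:
    """CLIP binding regions: TSV chrom, start, end, strand (1-based incl.)."""
    regions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, start, end, strand = line.rstrip("\n").split("\t")[:4]
            regions.append((chrom, int(start), int(end), strand))
    return regions


def annotate_clip_support(
    sites: list[MiRNASite],
    clip_regions: list[tuple[str, int, int, str]],
    circle: CircleSequence,
) -> list[MiRNASite]:
    """Mark sites whose genomic projection overlaps any CLIP region >= 1 nt."""
    trees: dict[tuple[str, str], IntervalTree] = {}
    for chrom, start, end, strand in clip_regions:
        trees.setdefault((chrom, strand), IntervalTree()).addi(start, end + 1)
    tree = trees.get((circle.chrom, circle.strand))
    if tree is None:
        return [replace(s, clip_supported=False) for s in sites]
    out = []
    for s in sites:
        supported = any(
            tree.overlap(a, b + 1) for a, b in site_genomic_intervals(circle, s)
        )
        out.append(replace(s, clip_supported=supported))
    return out


def collapse_to_interactions(sites: list[MiRNASite]) -> list[CircMiInteraction]:
    """Group filtered sites by (event, miRNA) into interaction records."""
    groups: dict[tuple[str, str], list[MiRNASite]] = {}
    for s in sites:
        groups.setdefault((s.event_id, s.mirna_id), []).append(s)
    out = []
    for (event_id, mirna_id), members in sorted(groups.items()):
        out.append(
            CircMiInteraction(
                event_id=event_id,
                mirna_id=mirna_id,
                n_sites=len(members),
                max_score=max(s.score for s in members),
                any_spans_junction=any(s.spans_junction for s in members),
                clip_supported=any(s.clip_supported for s in members),
            )
        )
    return out
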