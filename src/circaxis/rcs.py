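"""Reverse-complementary sequence (RCS) scanning in BSJ flanks.

Intronic reverse-complement pairs flanking circularized exons promote
back-splicing; pairs whose members sit in opposite flanks (RCS_across)
compete with pairs inside one flank (RCS_within), so the across/within
balance is informative about circularization propensity.  Flanks are the
+/- N genomic nucleotides around the back-splice sites (default N = 10000);
candidate pairs come from minus-strand local alignment and are retained
only when bitscore > 100, aligned length > 50 and identity > 80% — all
strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alignment import (
    DEFAULT_SCORING,
    AlignmentHit,
    ScoringScheme,
    _mostly_overlapping,
    bitscore,
    local_align,
)
from .reference import CircJunction, GenomeRef, extract_region, reverse_complement

DEFAULT_FLANK = 10_000


@dataclass(frozen=True)
class RCSThresholds:
    min_bitscore: float = 100.0
    min_length: int = 50
    min_identity: float = 0.80


DEFAULT_THRESHOLDS = RCSThresholds()


@dataclass(frozen=True)
class FlankPair:
    """Flanks in transcription orientation: upstream = 5' of the acceptor,
    downstream = 3' of the donor."""

    event_id: str
    upstream: str
    downstream: str
    n: int
    upstream_clipped: bool
    downstream_clipped: bool


@dataclass(frozen=True)
class RCSHit:
    """One retained reverse-complement pair.

    ``span_a``/``span_b`` are 1-based within their flank; for across-pairs
    span_a is in the upstream flank and span_b in the downstream flank, for
    within-pairs both are in the same flank with span_a.start < span_b.start.
    """

    kind: str  # across | within_upstream | within_downstream
    span_a: tuple[int, int]
    span_b: tuple[int, int]
    bits: float
    length: int
    identity: float


@dataclass(frozen=True)
class RCSSummary:
    event_id: str
    rcs_across: int
    rcs_within: int

    @property
    def delta(self) -> int:
        return self.rcs_across - self.rcs_within


def extract_flanks(circ: CircJunction, genome: GenomeRef, n: int = DEFAULT_FLANK) -> FlankPair:
    """+/- n nt windows outside the circle span, clipped at chromosome ends."""
    if n < 1:
        raise ValueError("flank size must be >= 1")
    if circ.strand == "+":
        up = extract_region(genome, circ.chrom, circ.acceptor_pos - n, circ.acceptor_pos - 1, "+")
        down = extract_region(genome, circ.chrom, circ.donor_pos + 1, circ.donor_pos + n, "+")
    else:
        up = extract_region(genome, circ.chrom, circ.acceptor_pos + 1, circ.acceptor_pos + n, "-")
        down = extract_region(genome, circ.chrom, circ.donor_pos - n, circ.donor_pos - 1, "-")
    return FlankPair(
        event_id=circ.event_id,
        upstream=up.seq,
        downstream=down.seq,
        n=n,
        upstream_clipped=up.clipped,
        downstream_clipped=down.clipped,
    )


def passes_thresholds(
    bits: float,
    length: int,
    identity: float,
    thresholds: RCSThresholds = DEFAULT_THRESHOLDS,
) -> bool:
    """Strict three-way retention rule for candidate RCS alignments."""
    return (
        bits > thresholds.min_bitscore
        and length > thresholds.min_length
        and identity > thresholds.min_identity
    )


def _qualifying(hits: list[AlignmentHit], scoring, thresholds) -> list[AlignmentHit]:
    passing = [
        h
        for h in hits
        if passes_thresholds(bitscore(h.raw_score, scoring), h.aligned_columns, h.identity, thresholds)
    ]
    # one biological RCS can be fragmented by seeding; merge near-duplicates
    passing.sort(key=lambda h: -h.raw_score)
    merged: list[AlignmentHit] = []
    for h in passing:
        if not any(_mostly_overlapping(h, other) for other in merged):
            merged.append(h)
    return merged


def find_rcs_across(
    pair: FlankPair,
    scoring: ScoringScheme = DEFAULT_SCORING,
    thresholds: RCSThresholds = DEFAULT_THRESHOLDS,
    seed_length: int = 11,
) -> list[RCSHit]:
    """RCS pairs with one member in each flank.

    The upstream flank is aligned against the reverse complement of the
    downstream flank (a minus-strand alignment); hit coordinates on the
    reverse-complemented side are folded back to downstream-flank positions.
    """
    if not pair.upstream or not pair.downstream:
        return []
    hits = local_align(
        pair.upstream,
        reverse_complement(pair.downstream),
        scoring=scoring,
        seed_length=seed_length,
    )
    out = []
    m = len(pair.downstream)
    for h in _qualifying(hits, scoring, thresholds):
        t = (m - h.target_span[1] + 1, m - h.target_span[0] + 1)
        out.append(
            RCSHit(
                kind="across",
                span_a=h.query_span,
                span_b=t,
                bits=bitscore(h.raw_score, scoring),
                length=h.aligned_columns,
                identity=h.identity,
            )
        )
    out.sort(key=lambda r: (r.span_a, r.span_b))
    return out


def find_rcs_within(
    flank: str,
    kind: str = "within_upstream",
    scoring: ScoringScheme = DEFAULT_SCORING,
    thresholds: RCSThresholds = DEFAULT_THRESHOLDS,
    seed_length: int = 11,
) -> list[RCSHit]:
    """RCS pairs whose two members lie inside one flank.

    The flank is aligned against its own reverse complement.  Each
    biological pair appears twice (mirror alignments) and a palindromic
    region can align onto itself; hits whose two members overlap are
    discarded and the remainder canonicalized (left member first) and
    deduplicated, so each pair is counted once.
    """
    if not flank:
        return []
    hits = local_align(
        flank, reverse_complement(flank), scoring=scoring, seed_length=seed_length
    )
    m = len(flank)
    out: list[RCSHit] = []
    for h in _qualifying(hits, scoring, thresholds):
        a = h.query_span
        b = (m - h.target_span[1] + 1, m - h.target_span[0] + 1)
        if a[0] <= b[1] and b[0] <= a[1]:
            continue  # self-overlapping (palindromic diagonal)
        if a[0] > b[0]:
            a, b = b, a
        candidate = RCSHit(
            kind=kind,
            span_a=a,
            span_b=b,
            bits=bitscore(h.raw_score, scoring),
            length=h.aligned_columns,
            identity=h.identity,
        )
        dup = any(
            _span_pair_overlap(candidate, prev) for prev in out
        )
        if not dup:
            out.append(candidate)
    out.sort(key=lambda r: (r.span_a, r.span_b))
    return out


def _span_pair_overlap(x: RCSHit, y: RCSHit, frac: float = 0.5) -> bool:
    def ov(a, b):
        inter = max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)
        shortest = min(a[1] - a[0], b[1] - b[0]) + 1
        return inter > frac * shortest

    return ov(x.span_a, y.span_a) and ov(x.span_b, y.span_b)


def summarize_rcs(
    event_id: str,
    across: list[RCSHit],
    within_up: list[RCSHit],
    within_down: list[RCSHit],
) -> RCSSummary:
    """Counts per event; within sums both flanks, delta = across - within."""
    return RCSSummary(
        event_id=event_id,
        rcs_across=len(across),
        rcs_within=len(within_up) + len(within_down),
    )
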