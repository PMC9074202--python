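"""Alignment-ambiguity screening of junction pseudo-reads.

A putative back-splice junction is a false-positive signature when its
junction pseudo-read can be explained by a contiguous (co-linear) alignment
somewhere else in the reference, or when it maps near-equally well to
multiple loci.  Both checks run under two seeding sensitivities (tile 11
and tile 9, mirroring the two BLAT parameter sets) and an event is retained
only if it is clean under both.

The event's own locus — the genomic region of its circle exons and any
transcript overlapping it — is exempt: every true circRNA maps to its own
locus non-co-linearly, and counting that mapping would flag everything.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alignment import (
    DEFAULT_PROFILE,
    DEFAULT_SCORING,
    SENSITIVE_PROFILE,
    AlignerProfile,
    AlignmentHit,
    ReferenceIndex,
    ScoringScheme,
    search_reference,
)
from .junctions import CircleSequence

ALT_COLINEAR_COVERAGE = 0.80
MULTI_HIT_SCORE_MARGIN = 3.0
_OWN_LOCUS_PAD = 10


@dataclass(frozen=True)
class ProfileFlags:
    alt_colinear: bool
    multiple_hits: bool

    @property
    def clean(self) -> bool:
        return not (self.alt_colinear or self.multiple_hits)


@dataclass(frozen=True)
class AmbiguityVerdict:
    event_id: str
    flags: tuple[tuple[str, ProfileFlags], ...]  # (profile name, flags)

    @property
    def retained(self) -> bool:
        return all(f.clean for _, f in self.flags)

    @property
    def alt_colinear(self) -> bool:
        return any(f.alt_colinear for _, f in self.flags)

    @property
    def multiple_hits(self) -> bool:
        """Multi-hit flag with alt-co-linear precedence for disjoint counts."""
        return not self.alt_colinear and any(f.multiple_hits for _, f in self.flags)


def _own_span(circle: CircleSequence) -> tuple[int, int]:
    lo = min(s for s, _ in circle.exon_spans) - _OWN_LOCUS_PAD
    hi = max(e for _, e in circle.exon_spans) + _OWN_LOCUS_PAD
    return lo, hi


def is_own_locus(hit: AlignmentHit, circle: CircleSequence, reference: ReferenceIndex) -> bool:
    """True when a hit lies on the event's own genomic locus (or a
    transcript overlapping it)."""
    lo, hi = _own_span(circle)
    if hit.target_kind == "genome":
        return hit.target_id == circle.chrom and hit.target_span[0] <= hi and hit.target_span[1] >= lo
    span = reference.transcript_spans.get(hit.target_id)
    if span is None:
        return False
    chrom, t_lo, t_hi = span
    return chrom == circle.chrom and t_lo <= hi and t_hi >= lo


def detect_alt_colinear(alt_hits: list[AlignmentHit], concat_len: int) -> bool:
    """Contiguous alternative explanation covering > 80% of the pseudo-read.

    Coverage is matches over the pseudo-read length, so only alignments
    accounting for most of the read qualify; the threshold is strict.
    """
    return any(
        (not h.split) and h.matches / concat_len > ALT_COLINEAR_COVERAGE for h in alt_hits
    )


def detect_multiple_hits(
    own_hits: list[AlignmentHit],
    alt_hits: list[AlignmentHit],
    margin: float = MULTI_HIT_SCORE_MARGIN,
) -> bool:
    """True when some alternative locus scores within ``margin`` of the best.

    The event is unambiguous only if its best (own-locus) alignment beats
    every alternative-locus alignment by at least ``margin`` score units.
    """
    if not alt_hits:
        return False
    if own_hits:
        ref_score = max(h.raw_score for h in own_hits)
        candidates = alt_hits
    else:
        ranked = sorted(alt_hits, key=lambda h: -h.raw_score)
        ref_score = ranked[0].raw_score
        best = ranked[0]
        candidates = [
            h
            for h in ranked[1:]
            if not (
                h.target_id == best.target_id
                and h.target_span[0] <= best.target_span[1]
                and h.target_span[1] >= best.target_span[0]
            )
        ]
    return any(ref_score - h.raw_score < margin for h in candidates)


def check_ambiguity(
    concat: str,
    circle: CircleSequence,
    reference: ReferenceIndex,
    profiles: tuple[AlignerProfile, ...] = (DEFAULT_PROFILE, SENSITIVE_PROFILE),
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> AmbiguityVerdict:
    """Run both detectors under every profile; retained means clean under all."""
    flags = []
    for profile in profiles:
        hits = search_reference(concat, reference, profile=profile, scoring=scoring,
                                query_id=circle.event_id)
        own = [h for h in hits if is_own_locus(h, circle, reference)]
        alt = [h for h in hits if not is_own_locus(h, circle, reference)]
        flags.append(
            (
                profile.name,
                ProfileFlags(
                    alt_colinear=detect_alt_colinear(alt, len(concat)),
                    multiple_hits=detect_multiple_hits(own, alt),
                ),
            )
        )
    return AmbiguityVerdict(event_id=circle.event_id, flags=tuple(flags))
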