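"""Back-splice junction validation against annotation, and circle sequences.

A credible exonic circRNA has both its donor and acceptor at annotated exon
boundaries of one common co-linear transcript.  For events that pass, the
putative exonic circle sequence is the transcription-order concatenation of
the transcript's exons between acceptor and donor (inclusive), and the
junction pseudo-read joins the last ~100 nt of the circle to its first
~100 nt so the back-splice junction sits mid-read.
"""

from __future__ import annotations

from dataclasses import dataclass

from .reference import CircJunction, GeneAnnotation, GenomeRef, reverse_complement

JUNCTION_ARM = 100


@dataclass(frozen=True)
class BsjCheckResult:
    event_id: str
    donor_annotated: bool
    acceptor_annotated: bool
    common_transcripts: tuple[str, ...]
    reason: str = ""

    @property
    def passed(self) -> bool:
        return bool(self.common_transcripts)


@dataclass(frozen=True)
class CircleSequence:
    event_id: str
    source_transcript_id: str
    chrom: str
    strand: str
    exon_spans: tuple[tuple[int, int], ...]  # genomic order
    sequence: str  # transcription orientation, acceptor-side first

    def __len__(self):
        return len(self.sequence)


def check_boundaries(circ: CircJunction, annotation: GeneAnnotation) -> BsjCheckResult:
    """Check both splice sites against annotated exon boundaries.

    The donor must be a transcription-orientation 3' exon end and the
    acceptor a 5' exon start, in at least one shared transcript on the
    event's strand.
    """
    donor_tx = annotation.donor_index.get((circ.chrom, circ.strand, circ.donor_pos), set())
    acceptor_tx = annotation.acceptor_index.get(
        (circ.chrom, circ.strand, circ.acceptor_pos), set()
    )
    common = tuple(sorted(donor_tx & acceptor_tx))
    reason = ""
    if not donor_tx and not acceptor_tx:
        reason = "no_annotated_boundary"
    elif not donor_tx:
        reason = "donor_not_annotated"
    elif not acceptor_tx:
        reason = "acceptor_not_annotated"
    elif not common:
        reason = "no_common_transcript"
    return BsjCheckResult(
        event_id=circ.event_id,
        donor_annotated=bool(donor_tx),
        acceptor_annotated=bool(acceptor_tx),
        common_transcripts=common,
        reason=reason,
    )


def _circle_exons(tx, circ: CircJunction) -> tuple[tuple[int, int], ...]:
    """Exons of ``tx`` between acceptor and donor inclusive, genomic order."""
    lo = min(circ.acceptor_pos, circ.donor_pos)
    hi = max(circ.acceptor_pos, circ.donor_pos)
    return tuple((s, e) for s, e in tx.exons if s >= lo and e <= hi)


def build_circle_sequence(
    circ: CircJunction,
    check: BsjCheckResult,
    annotation: GeneAnnotation,
    genome: GenomeRef,
) -> CircleSequence:
    """Build the exonic circle sequence for a validated event.

    When several transcripts carry both boundaries the one yielding the
    longest circle is used (ties broken by transcript_id) so the most
    inclusive exon model wins deterministically.
    """
    if not check.passed:
        raise ValueError(f"cannot build circle for failing event {circ.event_id}")
    candidates = []
    for tid in check.common_transcripts:
        tx = annotation.transcripts[tid]
        exons = _circle_exons(tx, circ)
        length = sum(e - s + 1 for s, e in exons)
        candidates.append((-length, tid, exons))
    candidates.sort()
    _, tid, exons = candidates[0]
    tx = annotation.transcripts[tid]
    seq = "".join(genome.fetch(circ.chrom, s, e) for s, e in exons)
    if circ.strand == "-":
        seq = reverse_complement(seq)
    return CircleSequence(
        event_id=circ.event_id,
        source_transcript_id=tid,
        chrom=circ.chrom,
        strand=circ.strand,
        exon_spans=exons,
        sequence=seq,
    )


def build_junction_concat(circle: CircleSequence, arm: int = JUNCTION_ARM) -> str:
    """Junction pseudo-read: last min(arm, L) nt + first min(arm, L) nt.

    Arms shorter than ``arm`` use the whole available arm without wrapping
    the circle a second time, so the pseudo-read never contains artificial
    tandem repetition.
    """
    seq = circle.sequence
    if not seq:
        raise ValueError("empty circle sequence")
    a = min(arm, len(seq))
    return seq[-a:] + seq[:a]
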