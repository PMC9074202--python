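"""Reference data model: genome, gene annotation, back-splice junctions, miRNAs.

All coordinates are 1-based inclusive (GTF convention) throughout the
package.  Sequences are stored in the DNA alphabet, upper case; ``U`` is
converted to ``T`` on ingest and ``N`` is allowed but never scores as a
match in any alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

from Bio import SeqIO

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"cannot complement characters {sorted(bad)!r}")
    return seq.translate(_COMPLEMENT)[::-1]


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


class Region(NamedTuple):
    """A genomic subsequence plus a flag set when the request was clipped."""

    seq: str
    clipped: bool


class GenomeRef:
    """In-memory genome: chromosome name -> normalized nucleotide string."""

    def __init__(self, chroms: dict[str, str] | None = None):
        self.chroms: dict[str, str] = {}
        if chroms:
            for name, seq in chroms.items():
                self.add(name, seq)

    def add(self, name: str, seq: str) -> None:
        if name in self.chroms:
            raise ValueError(f"duplicate chromosome name {name!r}")
        seq = _normalize(seq)
        if not seq:
            raise ValueError(f"chromosome {name!r} is empty")
        self.chroms[name] = seq

    def __contains__(self, name: str) -> bool:
        return name in self.chroms

    def length(self, name: str) -> int:
        return len(self.chroms[name])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Bases ``start..end`` (1-based inclusive) of ``chrom``; no clipping."""
        return self.chroms[chrom][start - 1 : end]


def extract_region(
    genome: GenomeRef, chrom: str, start: int, end: int, strand: str = "+"
) -> Region:
    """Extract a 1-based inclusive region, reverse-complemented on '-'.

    Out-of-range requests are clipped to the chromosome bounds and the
    returned :class:`Region` carries ``clipped=True`` — flank windows near
    chromosome ends rely on this.
    """
    if chrom not in genome:
        raise KeyError(f"unknown chromosome {chrom!r}")
    if start > end:
        raise ValueError(f"start {start} > end {end}")
    n = genome.length(chrom)
    cs, ce = max(1, start), min(n, end)
    clipped = (cs != start) or (ce != end)
    seq = genome.fetch(chrom, cs, ce) if cs <= ce else ""
    if strand == "-":
        seq = reverse_complement(seq)
    return Region(seq, clipped)


def read_genome_fasta(path) -> GenomeRef:
    """Load a (multi-)FASTA into a :class:`GenomeRef`.

    Case and U/T are normalized; duplicate record ids and empty files are
    errors.
    """
    genome = GenomeRef()
    for rec in SeqIO.parse(str(path), "fasta"):
        genome.add(rec.id, str(rec.seq))
    if not genome.chroms:
        raise ValueError(f"no FASTA records in {path}")
    return genome


# ---------------------------------------------------------------------------
# Gene annotation


@dataclass(frozen=True)
class TranscriptModel:
    transcript_id: str
    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # 1-based inclusive, genomic order

    def __post_init__(self):
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"exon start {s} > end {e} in {self.transcript_id}")
        starts = [s for s, _ in self.exons]
        ends = [e for _, e in self.exons]
        if any(starts[i + 1] <= ends[i] for i in range(len(self.exons) - 1)):
            raise ValueError(f"overlapping/unsorted exons in {self.transcript_id}")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def donor_boundaries(self) -> list[int]:
        """Genomic positions that are transcription-orientation 3' exon ends."""
        return [e for _, e in self.exons] if self.strand == "+" else [s for s, _ in self.exons]

    def acceptor_boundaries(self) -> list[int]:
        """Genomic positions that are transcription-orientation 5' exon starts."""
        return [s for s, _ in self.exons] if self.strand == "+" else [e for _, e in self.exons]


class GeneAnnotation:
    """Transcript models plus exact donor/acceptor boundary indices."""

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self.transcripts: dict[str, TranscriptModel] = {}
        # (chrom, strand, pos) -> set of transcript_ids
        self.donor_index: dict[tuple[str, str, int], set[str]] = {}
        self.acceptor_index: dict[tuple[str, str, int], set[str]] = {}
        for tx in transcripts:
            if tx.transcript_id in self.transcripts:
                raise ValueError(f"duplicate transcript_id {tx.transcript_id!r}")
            self.transcripts[tx.transcript_id] = tx
            for pos in tx.donor_boundaries():
                self.donor_index.setdefault((tx.chrom, tx.strand, pos), set()).add(
                    tx.transcript_id
                )
            for pos in tx.acceptor_boundaries():
                self.acceptor_index.setdefault((tx.chrom, tx.strand, pos), set()).add(
                    tx.transcript_id
                )

    def __iter__(self):
        return iter(self.transcripts.values())

    def __len__(self):
        return len(self.transcripts)


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out = {}
    for part in attr.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def read_annotation_gtf(path) -> GeneAnnotation:
    """Assemble transcript models from the exon features of a GTF file.

    Non-exon features are ignored; exon lines must carry ``transcript_id``
    and ``gene_id`` attributes.  Exons are stored sorted by genomic start
    regardless of the file order.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _, feature, start, end, _, strand, _, attrs = fields[:9]
            if feature != "exon":
                continue
            a = _parse_gtf_attributes(attrs)
            if "transcript_id" not in a:
                raise ValueError(f"{path}:{lineno}: exon lacks transcript_id")
            if "gene_id" not in a:
                raise ValueError(f"{path}:{lineno}: exon lacks gene_id")
            tid = a["transcript_id"]
            exons.setdefault(tid, []).append((int(start), int(end)))
            meta[tid] = (a["gene_id"], a.get("gene_name", a["gene_id"]), chrom, strand)
    transcripts = []
    for tid, ex in exons.items():
        gene_id, gene_name, chrom, strand = meta[tid]
        transcripts.append(
            TranscriptModel(tid, gene_id, gene_name, chrom, strand, tuple(sorted(ex)))
        )
    return GeneAnnotation(transcripts)


# ---------------------------------------------------------------------------
# Back-splice junctions


@dataclass(frozen=True)
class CircJunction:
    """One back-splice junction event.

    The donor is the transcriptionally downstream splice site joined back to
    the upstream acceptor, so on '+' the acceptor has the smaller genomic
    coordinate and on '-' the larger.
    """

    event_id: str
    chrom: str
    donor_pos: int
    acceptor_pos: int
    strand: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.strand == "+" and not self.acceptor_pos < self.donor_pos:
            raise ValueError("on '+' the acceptor must be upstream (smaller) of the donor")
        if self.strand == "-" and not self.acceptor_pos > self.donor_pos:
            raise ValueError("on '-' the acceptor must be upstream (larger) of the donor")


def make_junction(chrom: str, pos1: int, pos2: int, strand: str) -> CircJunction:
    """Build a junction from two coordinates, order-insensitively.

    The acceptor is the transcriptionally upstream site: the smaller
    coordinate on '+', the larger on '-'.
    """
    lo, hi = min(pos1, pos2), max(pos1, pos2)
    if strand == "+":
        acceptor, donor = lo, hi
    elif strand == "-":
        acceptor, donor = hi, lo
    else:
        raise ValueError(f"strand must be + or -, got {strand!r}")
    event_id = f"{chrom}:{lo}|{hi}:{strand}"
    return CircJunction(event_id, chrom, donor, acceptor, strand)


def read_circ_junctions(path, shift: int = 0) -> list[CircJunction]:
    """Read a BSJ table: TSV columns (chrom, pos1, pos2, strand).

    Duplicate rows are collapsed (count logged).  ``shift`` is added to both
    coordinates on ingest, for callers whose tables are 0-based.
    """
    seen: dict[tuple, CircJunction] = {}
    dups = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected >=4 tab-separated columns")
            chrom, p1, p2, strand = fields[0], fields[1], fields[2], fields[3]
            is_header = not (p1.lstrip("-").isdigit() and p2.lstrip("-").isdigit()) and strand not in ("+", "-")
            if lineno == 1 and is_header:
                continue  # header row
            try:
                pos1, pos2 = int(p1) + shift, int(p2) + shift
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer position") from exc
            circ = make_junction(chrom, pos1, pos2, strand)
            key = (circ.chrom, circ.donor_pos, circ.acceptor_pos, circ.strand)
            if key in seen:
                dups += 1
            else:
                seen[key] = circ
    if dups:
        log.warning("collapsed %d duplicate BSJ rows in %s", dups, path)
    return list(seen.values())


def write_circ_junctions(circs: Iterable[CircJunction], path) -> None:
    with open(path, "w") as fh:
        for c in circs:
            lo, hi = sorted((c.donor_pos, c.acceptor_pos))
            fh.write(f"{c.chrom}\t{lo}\t{hi}\t{c.strand}\n")


# ---------------------------------------------------------------------------
# miRNA registry


class MiRNARegistry:
    """Mature miRNA sequences keyed by id, stored in the DNA alphabet."""

    MIN_LEN = 15

    def __init__(self, entries: dict[str, str] | None = None):
        self.sequences: dict[str, str] = {}
        if entries:
            for name, seq in entries.items():
                self.add(name, seq)

    def add(self, mirna_id: str, seq: str) -> None:
        if mirna_id in self.sequences:
            raise ValueError(f"duplicate miRNA id {mirna_id!r}")
        seq = _normalize(seq)
        if len(seq) < self.MIN_LEN:
            raise ValueError(
                f"miRNA {mirna_id!r} is {len(seq)} nt; mature miRNAs must be >= {self.MIN_LEN}"
            )
        self.sequences[mirna_id] = seq

    def __getitem__(self, mirna_id: str) -> str:
        return self.sequences[mirna_id]

    def __iter__(self):
        return iter(self.sequences)

    def __len__(self):
        return len(self.sequences)

    def items(self):
        return self.sequences.items()


def read_mirna_fasta(path) -> MiRNARegistry:
    reg = MiRNARegistry()
    for rec in SeqIO.parse(str(path), "fasta"):
        reg.add(rec.id, str(rec.seq))
    if not len(reg):
        raise ValueError(f"no FASTA records in {path}")
    return reg
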