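"""Adapters for pre-computed external aligner outputs.

The pipeline can consume BLAT PSL files, tabular BLAST (outfmt 6, default
columns) and miRanda 3.3a text output in place of the built-in aligner and
scanner, so production runs can use the exact third-party tools while tests
never shell out.
"""

from __future__ import annotations

import math
from dataclasses import asdict

from .alignment import AlignmentHit, ScoringScheme, DEFAULT_SCORING
from .targeting import MiRNASite

_PSL_COLUMNS = 21


def parse_psl(path) -> list[AlignmentHit]:
    """Parse a 21-column PSL file (optionally with the psLayout header).

    PSL coordinates are 0-based half-open; they are converted to the
    package's 1-based inclusive spans.  Multi-block hits with inserted
    target bases are marked ``split`` (non-co-linear two-block mappings).
    The raw score is the BLAT web score: matches + repMatches - misMatches
    - qNumInsert - tNumInsert.
    """
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != _PSL_COLUMNS or not fields[0].isdigit():
                if line.startswith(("psLayout", "match", "-", " ")) or not line.strip():
                    continue  # header / separator
                raise ValueError(f"{path}:{lineno}: expected {_PSL_COLUMNS} PSL columns")
            (matches, mism, rep, _ncount, qnum, qbase, tnum, tbase, strand, qname,
             _qsize, qstart, qend, tname, _tsize, tstart, tend, blocks, *_rest) = fields
            hits.append(
                AlignmentHit(
                    query_id=qname,
                    target_id=tname,
                    target_kind="genome",
                    strand=strand[0],
                    query_span=(int(qstart) + 1, int(qend)),
                    target_span=(int(tstart) + 1, int(tend)),
                    matches=int(matches) + int(rep),
                    mismatches=int(mism),
                    gap_bases=int(qbase) + int(tbase),
                    raw_score=float(
                        int(matches) + int(rep) - int(mism) - int(qnum) - int(tnum)
                    ),
                    split=int(blocks) > 1 and int(tbase) > 0,
                )
            )
    return hits


def parse_blast_tab(path, scoring: ScoringScheme = DEFAULT_SCORING) -> list[AlignmentHit]:
    """Parse tabular BLAST (outfmt 6 default 12 columns).

    Match/mismatch/gap columns are reconstructed from pident, length and
    mismatch; the stored raw score is back-computed from the reported
    bitscore so downstream bitscore thresholds reproduce the file's values.
    Subject coordinates with sstart > send indicate a minus-strand hit.
    """
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}:{lineno}: expected >=12 BLAST outfmt-6 columns")
            try:
                (qid, sid, pident, length, mism, _gapopen, qstart, qend,
                 sstart, send, _evalue, bits) = fields[:12]
                length, mism = int(length), int(mism)
                matches = round(float(pident) / 100.0 * length)
                sstart, send = int(sstart), int(send)
                strand = "+" if sstart <= send else "-"
                raw = (float(bits) * math.log(2) + math.log(scoring.k)) / scoring.lam
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable BLAST line") from exc
            hits.append(
                AlignmentHit(
                    query_id=qid,
                    target_id=sid,
                    target_kind="genome",
                    strand=strand,
                    query_span=(int(qstart), int(qend)),
                    target_span=(min(sstart, send), max(sstart, send)),
                    matches=matches,
                    mismatches=mism,
                    gap_bases=length - matches - mism,
                    raw_score=raw,
                )
            )
    return hits


def parse_miranda(path) -> list[MiRNASite]:
    """Parse miRanda 3.3a text output into binding-site records.

    Hit lines start with a single '>' (summary lines with '>>' are
    aggregates and skipped):

        >miRNA_id <TAB> target_id <TAB> score <TAB> energy <TAB> q_beg q_end
        <TAB> t_beg t_end <TAB> align_len <TAB> identity% <TAB> similarity%

    Target coordinates are taken as 1-based circle positions; the caller
    decides junction spanning from its own geometry.
    """
    sites = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.startswith(">") or line.startswith(">>"):
                continue
            fields = line[1:].rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: unparseable miRanda hit line")
            try:
                mirna_id = fields[0].strip()
                target_id = fields[1].strip()
                score = float(fields[2])
                energy = float(fields[3])
                t_beg, t_end = (int(x) for x in fields[5].split())
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable miRanda hit line") from exc
            sites.append(
                MiRNASite(
                    event_id=target_id,
                    mirna_id=mirna_id,
                    start=t_beg,
                    end=t_end,
                    score=score,
                    energy=energy,
                    spans_junction=t_beg > t_end,
                )
            )
    return sites


_HIT_FIELDS = [
    "query_id", "target_id", "target_kind", "strand",
    "query_start", "query_end", "target_start", "target_end",
    "matches", "mismatches", "gap_bases", "raw_score", "split",
]


def write_hits_tsv(hits: list[AlignmentHit], path) -> None:
    """Write hits to a PSL-like TSV that round-trips all AlignmentHit fields."""
    with open(path, "w") as fh:
        fh.write("\t".join(_HIT_FIELDS) + "\n")
        for h in hits:
            d = asdict(h)
            row = [
                d["query_id"], d["target_id"], d["target_kind"], d["strand"],
                str(h.query_span[0]), str(h.query_span[1]),
                str(h.target_span[0]), str(h.target_span[1]),
                str(h.matches), str(h.mismatches), str(h.gap_bases),
                repr(h.raw_score), "1" if h.split else "0",
            ]
            fh.write("\t".join(row) + "\n")


def read_hits_tsv(path) -> list[AlignmentHit]:
    hits = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _HIT_FIELDS:
            raise ValueError(f"{path}: unexpected hit-table header")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            hits.append(
                AlignmentHit(
                    query_id=f[0], target_id=f[1], target_kind=f[2], strand=f[3],
                    query_span=(int(f[4]), int(f[5])),
                    target_span=(int(f[6]), int(f[7])),
                    matches=int(f[8]), mismatches=int(f[9]), gap_bases=int(f[10]),
                    raw_score=float(f[11]), split=f[12] == "1",
                )
            )
    return hits
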