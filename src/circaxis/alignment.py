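"""Seed-and-extend local alignment with affine gaps.

This is the package's built-in stand-in for the external aligners a
production run would use (BLAT for junction-ambiguity screening, blastn for
reverse-complement scanning): candidate regions are found by exact k-mer
seeding and then resolved with a full affine-gap Smith-Waterman pass over a
window around the seeds, so within a seeded window the reported score is the
true local optimum.  A length-L gap costs ``gap_open + (L-1)*gap_extend``.
``N`` never matches anything (including ``N``).

Raw scores are converted to bits with the Karlin-Altschul transform
``(lambda*S - ln K) / ln 2`` using the classical ungapped blastn constants
for +2/-3 scoring, which makes bitscore thresholds meaningful for the
built-in path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .reference import reverse_complement

# ---------------------------------------------------------------------------
# Scoring


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch/affine-gap scores plus Karlin-Altschul constants."""

    match: int = 2
    mismatch: int = 3  # penalty, positive
    gap_open: int = 5  # penalty for the first gapped base
    gap_extend: int = 2  # penalty per further gapped base
    lam: float = 0.625
    k: float = 0.41

    def __post_init__(self):
        if self.match <= 0 or self.mismatch <= 0 or self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("scores/penalties must be positive")
        if self.lam <= 0 or self.k <= 0:
            raise ValueError("Karlin-Altschul constants must be positive")


DEFAULT_SCORING = ScoringScheme()


def bitscore(raw_score: float, scoring: ScoringScheme = DEFAULT_SCORING) -> float:
    """Karlin-Altschul bitscore of a raw alignment score."""
    return (scoring.lam * raw_score - math.log(scoring.k)) / math.log(2)


@dataclass(frozen=True)
class AlignerProfile:
    """A named sensitivity profile of the seeding stage.

    ``seed_length`` mirrors BLAT's tile size; ``max_hits_reported`` caps the
    hit list the way repMatch caps repetitive seeds.
    """

    name: str
    seed_length: int
    min_seed_hits: int = 1
    max_hits_reported: int = 1024

    def __post_init__(self):
        if self.seed_length < 7:
            raise ValueError("seed_length must be >= 7")


#: BLAT-like default sensitivity (tile 11).
DEFAULT_PROFILE = AlignerProfile("default", seed_length=11, max_hits_reported=1024)
#: BLAT-like sensitive re-check (tile 9).
SENSITIVE_PROFILE = AlignerProfile("sensitive", seed_length=9, max_hits_reported=32768)


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment between a query and a target sequence.

    Spans are 1-based inclusive.  ``split`` marks hits whose target side
    consists of two discontiguous blocks (a non-co-linear mapping).
    """

    query_id: str
    target_id: str
    target_kind: str  # "genome" | "transcript" | "query"
    strand: str
    query_span: tuple[int, int]
    target_span: tuple[int, int]
    matches: int
    mismatches: int
    gap_bases: int
    raw_score: float
    split: bool = False

    @property
    def aligned_columns(self) -> int:
        return self.matches + self.mismatches + self.gap_bases

    @property
    def identity(self) -> float:
        cols = self.aligned_columns
        return self.matches / cols if cols else 0.0


# ---------------------------------------------------------------------------
# Smith-Waterman kernel

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_CODE[b] for b in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"unknown base {exc.args[0]!r}") from exc


@njit(cache=True)
def _fill(q, t, match, mismatch, gap_open, gap_extend):  # pragma: no cover - numba
    n, m = len(q), len(t)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), -1_000_000, dtype=np.int32)
    F = np.full((n + 1, m + 1), -1_000_000, dtype=np.int32)
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - gap_open, E[i, j - 1] - gap_extend)
            F[i, j] = max(H[i - 1, j] - gap_open, F[i - 1, j] - gap_extend)
            qa, tb = q[i - 1], t[j - 1]
            s = match if (qa == tb and qa < 4) else -mismatch
            h = H[i - 1, j - 1] + s
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best, bi, bj = h, i, j
    return H, E, F, best, bi, bj


def _traceback(H, E, F, q, t, bi, bj, scoring):
    """Walk back from the best cell; returns spans and column counts."""
    i, j = bi, bj
    matches = mismatches = gaps = 0
    state = "H"
    while True:
        if state == "H":
            if H[i, j] == 0:
                break
            qa, tb = q[i - 1], t[j - 1]
            s = scoring.match if (qa == tb and qa < 4) else -scoring.mismatch
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + s:
                if qa == tb and qa < 4:
                    matches += 1
                else:
                    mismatches += 1
                i, j = i - 1, j - 1
            elif H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":  # gap in query, consumes target base
            gaps += 1
            if E[i, j] == H[i, j - 1] - scoring.gap_open:
                state = "H"
            j -= 1
        else:  # gap in target, consumes query base
            gaps += 1
            if F[i, j] == H[i - 1, j] - scoring.gap_open:
                state = "H"
            i -= 1
    return (i + 1, bi), (j + 1, bj), matches, mismatches, gaps


def smith_waterman(query: str, target: str, scoring: ScoringScheme = DEFAULT_SCORING):
    """Full-matrix local alignment; returns the best hit or ``None``.

    Used internally to resolve seeded windows; quadratic, so callers keep
    the inputs windowed.
    """
    if not query:
        raise ValueError("empty query")
    if not target:
        return None
    q, t = encode(query), encode(target)
    H, E, F, best, bi, bj = _fill(
        q, t, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
    )
    if best <= 0:
        return None
    qspan, tspan, matches, mismatches, gaps = _traceback(H, E, F, q, t, bi, bj, scoring)
    return AlignmentHit(
        query_id="query",
        target_id="target",
        target_kind="query",
        strand="+",
        query_span=qspan,
        target_span=tspan,
        matches=matches,
        mismatches=mismatches,
        gap_bases=gaps,
        raw_score=float(best),
    )


# ---------------------------------------------------------------------------
# Seeding


class KmerIndex:
    """Exact k-mer position index of one target sequence."""

    def __init__(self, seq: str, k: int):
        self.seq = seq
        self.k = k
        self.index: dict[str, list[int]] = {}
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            self.index.setdefault(kmer, []).append(i)

    def seeds(self, query: str) -> list[tuple[int, int]]:
        """(query_pos, target_pos) 0-based pairs of exact k-mer matches."""
        out = []
        k = self.k
        for i in range(len(query) - k + 1):
            kmer = query[i : i + k]
            if "N" in kmer:
                continue
            for j in self.index.get(kmer, ()):
                out.append((i, j))
        return out


_WINDOW_PAD = 40
_MAX_DIAG_DRIFT = 15
_MAX_SEED_GAP = 100
_MAX_HITS_PER_WINDOW = 10
_FULL_DP_LIMIT = 40_000  # query*target cells below which the whole matrix is solved


def _cluster_seeds(seeds: list[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    """Group seed matches into candidate windows by diagonal proximity."""
    if not seeds:
        return []
    seeds = sorted(seeds, key=lambda s: (s[1] - s[0], s[0]))
    clusters: list[list[tuple[int, int]]] = [[seeds[0]]]
    for s in seeds[1:]:
        prev = clusters[-1][-1]
        same_band = abs((s[1] - s[0]) - (prev[1] - prev[0])) <= _MAX_DIAG_DRIFT
        nearby = abs(s[0] - prev[0]) <= _MAX_SEED_GAP
        if same_band and nearby:
            clusters[-1].append(s)
        else:
            clusters.append([s])
    return clusters


def _merge_windows(windows: list[tuple[int, int, int, int]]) -> list[tuple[int, int, int, int]]:
    """Merge overlapping rectangular windows to avoid duplicated DP work."""
    windows = sorted(windows)
    merged = [windows[0]]
    for w in windows[1:]:
        q0, q1, t0, t1 = merged[-1]
        if w[0] <= q1 and w[2] <= t1 and w[3] >= t0:
            merged[-1] = (q0, max(q1, w[1]), min(t0, w[2]), max(t1, w[3]))
        else:
            merged.append(w)
    return merged


def _spans_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def _mostly_overlapping(h1: AlignmentHit, h2: AlignmentHit, frac: float = 0.5) -> bool:
    qo = _spans_overlap(h1.query_span, h2.query_span)
    to = _spans_overlap(h1.target_span, h2.target_span)
    ql = min(h1.query_span[1] - h1.query_span[0], h2.query_span[1] - h2.query_span[0]) + 1
    tl = min(h1.target_span[1] - h1.target_span[0], h2.target_span[1] - h2.target_span[0]) + 1
    return qo > frac * ql and to > frac * tl


def local_align(
    query: str,
    target: str,
    scoring: ScoringScheme = DEFAULT_SCORING,
    seed_length: int = 11,
    min_score: int | None = None,
    query_id: str = "query",
    target_id: str = "target",
    target_kind: str = "query",
    strand: str = "+",
    index: KmerIndex | None = None,
) -> list[AlignmentHit]:
    """Seeded local alignment of ``query`` against ``target`` (one strand).

    Reports non-overlapping local hits scoring at least ``min_score``
    (default: the score of a bare seed, ``match * seed_length``).  Within a
    seeded window, secondary hits are recovered by masking the query span of
    each reported alignment and re-aligning (Waterman-Eggert style).
    """
    if not query:
        raise ValueError("empty query")
    if min_score is None:
        min_score = scoring.match * seed_length
    if len(query) < seed_length or len(target) < seed_length:
        return []
    idx = index if index is not None and index.k == seed_length else KmerIndex(target, seed_length)
    seeds = idx.seeds(query)
    if not seeds:
        return []
    k = seed_length
    if len(query) * len(target) <= _FULL_DP_LIMIT:
        # cheap enough to resolve exactly over the whole matrix
        windows = [(0, len(query), 0, len(target))]
        return _align_windows(query, target, windows, scoring, min_score,
                              query_id, target_id, target_kind, strand)
    windows = []
    for cluster in _cluster_seeds(seeds):
        q0 = max(0, min(s[0] for s in cluster) - _WINDOW_PAD)
        q1 = min(len(query), max(s[0] for s in cluster) + k + _WINDOW_PAD)
        t0 = max(0, min(s[1] for s in cluster) - _WINDOW_PAD)
        t1 = min(len(target), max(s[1] for s in cluster) + k + _WINDOW_PAD)
        windows.append((q0, q1, t0, t1))
    return _align_windows(query, target, _merge_windows(windows), scoring, min_score,
                          query_id, target_id, target_kind, strand)


def _align_windows(
    query: str,
    target: str,
    windows: list[tuple[int, int, int, int]],
    scoring: ScoringScheme,
    min_score: int,
    query_id: str,
    target_id: str,
    target_kind: str,
    strand: str,
) -> list[AlignmentHit]:
    hits: list[AlignmentHit] = []
    for q0, q1, t0, t1 in windows:
        sub_q = list(query[q0:q1])
        sub_t = target[t0:t1]
        for _ in range(_MAX_HITS_PER_WINDOW):
            hit = smith_waterman("".join(sub_q), sub_t, scoring)
            if hit is None or hit.raw_score < min_score:
                break
            shifted = replace(
                hit,
                query_id=query_id,
                target_id=target_id,
                target_kind=target_kind,
                strand=strand,
                query_span=(hit.query_span[0] + q0, hit.query_span[1] + q0),
                target_span=(hit.target_span[0] + t0, hit.target_span[1] + t0),
            )
            hits.append(shifted)
            for p in range(hit.query_span[0] - 1, hit.query_span[1]):
                sub_q[p] = "N"
    # windows may abut: drop near-duplicate hits, best first
    hits.sort(key=lambda h: -h.raw_score)
    kept: list[AlignmentHit] = []
    for h in hits:
        if not any(_mostly_overlapping(h, other) for other in kept):
            kept.append(h)
    return kept


# ---------------------------------------------------------------------------
# Reference search (genome + spliced transcripts, both strands)


@dataclass
class _Target:
    target_id: str
    kind: str  # genome | transcript
    seq: str


class ReferenceIndex:
    """Search targets (chromosomes + spliced transcripts) with k-mer caches."""

    def __init__(self, genome, annotation=None):
        self.targets: list[_Target] = []
        for chrom in sorted(genome.chroms):
            self.targets.append(_Target(chrom, "genome", genome.chroms[chrom]))
        if annotation is not None:
            for tx in sorted(annotation.transcripts):
                model = annotation.transcripts[tx]
                seq = "".join(genome.fetch(model.chrom, s, e) for s, e in model.exons)
                if model.strand == "-":
                    seq = reverse_complement(seq)
                self.targets.append(_Target(tx, "transcript", seq))
        self._cache: dict[tuple[str, str, int], KmerIndex] = {}
        # genomic span of each transcript, for own-locus bookkeeping
        self.transcript_spans: dict[str, tuple[str, int, int]] = {}
        if annotation is not None:
            for tx in annotation:
                self.transcript_spans[tx.transcript_id] = (tx.chrom, *tx.span)

    def kmer_index(self, target: _Target, strand: str, k: int) -> KmerIndex:
        key = (target.target_id, strand, k)
        if key not in self._cache:
            seq = target.seq if strand == "+" else reverse_complement(target.seq)
            self._cache[key] = KmerIndex(seq, k)
        return self._cache[key]


def _flip_span(span: tuple[int, int], length: int) -> tuple[int, int]:
    return (length - span[1] + 1, length - span[0] + 1)


def chain_split_hits(hits: list[AlignmentHit], query_len: int) -> list[AlignmentHit]:
    """Combine co-linear pairs of contiguous hits into split (two-block) hits.

    Two hits on the same target and strand whose query spans tile the query
    (adjacent within a small tolerance) and whose target blocks are
    discontiguous represent one non-co-linear mapping; the combined hit is
    appended with ``split=True``.
    """
    out = list(hits)
    contiguous = [h for h in hits if not h.split]
    for a in contiguous:
        for b in contiguous:
            if a is b or a.target_id != b.target_id or a.strand != b.strand:
                continue
            if not (a.query_span[1] < b.query_span[1]):
                continue
            junction_gap = b.query_span[0] - a.query_span[1] - 1
            if abs(junction_gap) > 10:
                continue
            tgap = (
                b.target_span[0] - a.target_span[1] - 1
                if a.target_span[1] < b.target_span[0]
                else a.target_span[0] - b.target_span[1] - 1
            )
            if tgap < 1:
                continue
            out.append(
                AlignmentHit(
                    query_id=a.query_id,
                    target_id=a.target_id,
                    target_kind=a.target_kind,
                    strand=a.strand,
                    query_span=(a.query_span[0], b.query_span[1]),
                    target_span=(
                        min(a.target_span[0], b.target_span[0]),
                        max(a.target_span[1], b.target_span[1]),
                    ),
                    matches=a.matches + b.matches,
                    mismatches=a.mismatches + b.mismatches,
                    gap_bases=a.gap_bases + b.gap_bases,
                    raw_score=a.raw_score + b.raw_score,
                    split=True,
                )
            )
    return out


def search_reference(
    query: str,
    reference: ReferenceIndex,
    profile: AlignerProfile = DEFAULT_PROFILE,
    scoring: ScoringScheme = DEFAULT_SCORING,
    query_id: str = "query",
) -> list[AlignmentHit]:
    """Align a query against every chromosome and spliced transcript.

    Both strands are searched; '-'-strand hit coordinates are reported on
    the forward target.  Contiguous hit pairs that jointly explain the query
    across a target gap are additionally reported as split hits.  Hits are
    sorted by raw score descending, ties broken by (target_id, position).
    """
    hits: list[AlignmentHit] = []
    for target in reference.targets:
        for strand in "+-":
            idx = reference.kmer_index(target, strand, profile.seed_length)
            found = local_align(
                query,
                idx.seq,
                scoring=scoring,
                seed_length=profile.seed_length,
                query_id=query_id,
                target_id=target.target_id,
                target_kind=target.kind,
                strand=strand,
                index=idx,
            )
            if strand == "-":
                found = [
                    replace(h, target_span=_flip_span(h.target_span, len(target.seq)))
                    for h in found
                ]
            hits.extend(found)
    hits = chain_split_hits(hits, len(query))
    hits.sort(key=lambda h: (-h.raw_score, h.target_id, h.target_span[0]))
    return hits[: profile.max_hits_reported]
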