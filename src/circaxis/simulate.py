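"""Deterministic synthetic references with planted ground truth.

Builds toy genomes, multi-exon gene annotations, BSJ tables, miRNA
registries and evidence tables so that every pipeline stage can be tested
against a known manifest without downloading any real resource.  The
background sequence is uniform-random but verified single-copy (no 40-mer
occurs twice), so ambiguity and RCS negatives are guaranteed rather than
probabilistic, and miRNA seeds are chosen absent from all unplanted circle
sequences, so scanner negatives are guaranteed too.

Planted features:

* ``plant_duplication`` — copies the event's junction pseudo-read (optionally
  identity-degraded with evenly spaced substitutions that defeat 11-mer but
  not 9-mer seeding) to an intergenic locus: a co-linear alternative
  explanation.
* ``plant_multihit`` — copies the pseudo-read's two arms with an intervening
  gap: a second non-co-linear locus scoring exactly like the event's own.
* ``plant_rcs`` — writes reverse-complement segment pairs into the BSJ
  flanks, across flanks or within one flank, at an exact identity
  (evenly spaced substitutions).
* ``plant_mirna_site`` — writes the reverse complement of a miRNA (or of a
  seed-only degenerate) into a circle, optionally across the back-splice
  junction.

All drawing goes through one numpy Generator, so the same seed and the
same sequence of calls give a byte-identical bundle.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .junctions import build_circle_sequence, build_junction_concat, check_boundaries
from .reference import (
    CircJunction,
    GeneAnnotation,
    GenomeRef,
    MiRNARegistry,
    TranscriptModel,
    make_junction,
    reverse_complement,
)
from .targeting import SEED_END, SEED_START, circle_position_to_genomic

_BASES = "ACGT"
_UNIQUE_K = 40


@dataclass(frozen=True)
class FixtureConfig:
    seed: int = 1
    n_chroms: int = 2
    chrom_len: int = 100_000
    n_genes: int = 6
    exons_per_gene: int = 3
    exon_len: tuple[int, int] = (120, 200)
    intron_len: tuple[int, int] = (250, 400)
    gene_margin: int = 6_400  # >= 2*flank_n so neighbouring flank windows stay disjoint
    flank_n: int = 3_000  # flank window the RCS plants assume
    n_mirnas: int = 3
    mirna_len: tuple[int, int] = (21, 23)


class FixtureError(ValueError):
    pass


def _degrade(seq: str, identity: float) -> str:
    """Substitute evenly spaced positions so achieved identity is exact.

    Substituted bases are shifted one step in the alphabet, which never
    recreates the original base.
    """
    n = len(seq)
    k = round(n * (1.0 - identity))
    if k == 0:
        return seq
    out = list(seq)
    for j in range(k):
        i = int((j + 0.5) * n / k)
        out[i] = _BASES[(_BASES.index(out[i]) + 1) % 4]
    return "".join(out)


def _degrade_every(seq: str, step: int) -> str:
    """Substitute every ``step``-th base (breaks all ``step``+1 length words)."""
    out = list(seq)
    for i in range(step - 1, len(seq), step):
        out[i] = _BASES[(_BASES.index(out[i]) + 1) % 4]
    return "".join(out)


class ToyFixture:
    """A mutable fixture bundle under construction.

    Build order matters only in that reading circle sequences reflects all
    plants made so far; the canonical builders below fix a deterministic
    call order.
    """

    def __init__(self, config: FixtureConfig = FixtureConfig()):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self._chroms: dict[str, list[str]] = {}
        self.transcripts: list[TranscriptModel] = []
        self.circs: list[CircJunction] = []
        self.mirnas = MiRNARegistry()
        self.mimr_rows: list[tuple[str, str, str]] = []  # (mirna, gene, label)
        self.clip_regions: list[tuple[str, int, int, str]] = []
        self.truth: dict = {"events": {}, "mimr": [], "subthreshold_rcs": {}}
        self._plants: list[tuple[str, int, int]] = []  # reserved intervals
        self._flank_cursor: dict[tuple[str, str], int] = {}
        self._dump_cursor: dict[str, int] = {}
        self._build_reference()

    # -- construction -------------------------------------------------

    def _random_seq(self, n: int) -> str:
        return "".join(self.rng.choice(list(_BASES), size=n))

    def _build_reference(self) -> None:
        cfg = self.config
        for ci in range(cfg.n_chroms):
            name = f"chr{ci + 1}"
            for _attempt in range(5):
                seq = self._random_seq(cfg.chrom_len)
                if self._single_copy_ok(seq):
                    break
            else:  # pragma: no cover - astronomically unlikely
                raise FixtureError("could not generate single-copy background")
            self._chroms[name] = list(seq)
            self._dump_cursor[name] = cfg.chrom_len - 100
        self._check_cross_chrom_unique()
        # place genes round-robin over chromosomes, alternating strand
        span_max = (
            cfg.exons_per_gene * cfg.exon_len[1]
            + (cfg.exons_per_gene - 1) * cfg.intron_len[1]
        )
        slot = span_max + cfg.gene_margin
        per_chrom = (cfg.chrom_len - 2 * cfg.gene_margin) // slot
        if cfg.n_genes > per_chrom * cfg.n_chroms:
            raise FixtureError("config demands more gene slots than the chromosomes hold")
        for gi in range(cfg.n_genes):
            chrom = f"chr{gi % cfg.n_chroms + 1}"
            slot_idx = gi // cfg.n_chroms
            start = cfg.gene_margin + slot_idx * slot + 1
            strand = "+" if gi % 2 == 0 else "-"
            exons = []
            pos = start
            for _ in range(cfg.exons_per_gene):
                elen = int(self.rng.integers(cfg.exon_len[0], cfg.exon_len[1] + 1))
                exons.append((pos, pos + elen - 1))
                ilen = int(self.rng.integers(cfg.intron_len[0], cfg.intron_len[1] + 1))
                pos += elen + ilen
            tx = TranscriptModel(
                transcript_id=f"TX{gi:03d}",
                gene_id=f"G{gi:03d}",
                gene_name=f"GENE{gi}",
                chrom=chrom,
                strand=strand,
                exons=tuple(exons),
            )
            self.transcripts.append(tx)
            lo, hi = tx.span
            self.circs.append(make_junction(chrom, lo, hi, strand))
        for circ, tx in zip(self.circs, self.transcripts):
            self.truth["events"][circ.event_id] = {
                "gene": tx.gene_id,
                "transcript": tx.transcript_id,
                "alt_colinear": False,
                "multiple_hits": False,
                "retained": True,
                "rcs_across": 0,
                "rcs_within": 0,
                "sites": [],
            }

    def _single_copy_ok(self, seq: str) -> bool:
        seen = set()
        for i in range(len(seq) - _UNIQUE_K + 1):
            w = seq[i : i + _UNIQUE_K]
            if w in seen:
                return False
            seen.add(w)
        return True

    def _check_cross_chrom_unique(self) -> None:
        seen: set[str] = set()
        for seq_list in self._chroms.values():
            seq = "".join(seq_list)
            for i in range(len(seq) - _UNIQUE_K + 1):
                w = seq[i : i + _UNIQUE_K]
                if w in seen:  # pragma: no cover
                    raise FixtureError("duplicated 40-mer across chromosomes")
                seen.add(w)

    # -- views ---------------------------------------------------------

    def genome(self) -> GenomeRef:
        return GenomeRef({name: "".join(seq) for name, seq in self._chroms.items()})

    def annotation(self) -> GeneAnnotation:
        return GeneAnnotation(self.transcripts)

    def circle(self, event_index: int) -> CircleSequence:
        circ = self.circs[event_index]
        check = check_boundaries(circ, self.annotation())
        return build_circle_sequence(circ, check, self.annotation(), self.genome())

    # -- low-level writes ----------------------------------------------

    def _write(self, chrom: str, start: int, seq: str, allow_exons: bool = False) -> None:
        end = start + len(seq) - 1
        if start < 1 or end > self.config.chrom_len:
            raise FixtureError(f"write outside {chrom}: {start}-{end}")
        for c, s, e in self._plants:
            if c == chrom and s <= end and start <= e:
                raise FixtureError(f"planted features overlap on {chrom}:{start}-{end}")
        if not allow_exons:
            for tx in self.transcripts:
                if tx.chrom == chrom:
                    for s, e in tx.exons:
                        if s <= end and start <= e:
                            raise FixtureError("plant would overwrite an exon")
        self._plants.append((chrom, start, end))
        self._chroms[chrom][start - 1 : end] = list(seq)

    # spacing between consecutive flank plants; wide enough that bridging
    # two 60-nt plants in one local alignment always scores worse than
    # stopping at the first (gap or mismatch cost over the spacer exceeds
    # the second plant's gain), so each planted pair yields its own hit
    _FLANK_SPACING = 250

    def _write_flank(self, event_index: int, which: str, seq: str) -> int:
        """Write ``seq`` so the extracted flank contains it; returns the
        distance of its junction-proximal edge from the back-splice site."""
        circ = self.circs[event_index]
        key = (circ.event_id, which)
        d = self._flank_cursor.get(key, 50)
        l = len(seq)
        if d + l > self.config.flank_n:
            raise FixtureError(f"insufficient {which} flank space for event {circ.event_id}")
        if which == "up":
            if circ.strand == "+":
                self._write(circ.chrom, circ.acceptor_pos - d - l, seq)
            else:
                self._write(circ.chrom, circ.acceptor_pos + d + 1, reverse_complement(seq))
        elif which == "down":
            if circ.strand == "+":
                self._write(circ.chrom, circ.donor_pos + d + 1, seq)
            else:
                self._write(circ.chrom, circ.donor_pos - d - l, reverse_complement(seq))
        else:
            raise ValueError("flank must be 'up' or 'down'")
        self._flank_cursor[key] = d + l + self._FLANK_SPACING
        return d

    def _dump_write(self, seq: str, chrom: str | None = None) -> tuple[str, int]:
        """Write into the gene-free tail of a chromosome; returns locus."""
        chrom = chrom or f"chr{self.config.n_chroms}"
        end = self._dump_cursor[chrom]
        start = end - len(seq) + 1
        self._write(chrom, start, seq)
        self._dump_cursor[chrom] = start - 101
        return chrom, start

    # -- plants ----------------------------------------------------------

    def plant_duplication(self, event_index: int, sensitive_only: bool = False) -> None:
        """Plant a co-linear alternative explanation of the pseudo-read.

        ``sensitive_only`` degrades the copy with a substitution every 10 nt
        so no 11-mer survives but 9-mer seeding still finds it (identity
        90%, above the 80% co-linear coverage cutoff).
        """
        concat = build_junction_concat(self.circle(event_index))
        copy = _degrade_every(concat, 10) if sensitive_only else concat
        self._dump_write(copy)
        entry = self.truth["events"][self.circs[event_index].event_id]
        entry["alt_colinear"] = True
        entry["retained"] = False
        entry["sensitive_only"] = sensitive_only

    def plant_multihit(self, event_index: int, gap: int = 500, pad: int = 12) -> None:
        """Plant a second non-co-linear locus scoring like the event's own.

        The two pseudo-read arms are copied from their genomic context with
        ``pad`` extra flanking bases, so the planted locus reproduces any
        chance extension the own locus offers and never scores lower.
        """
        circ = self.circs[event_index]
        circle = self.circle(event_index)
        arm = min(100, len(circle))
        chrom_seq = "".join(self._chroms[circ.chrom])
        if circ.strand == "+":
            donor_block = chrom_seq[circ.donor_pos - arm - pad - 1 : circ.donor_pos + pad]
            acceptor_block = chrom_seq[circ.acceptor_pos - pad - 1 : circ.acceptor_pos + arm + pad - 1]
        else:
            donor_block = reverse_complement(
                chrom_seq[circ.donor_pos - pad - 1 : circ.donor_pos + arm + pad - 1]
            )
            acceptor_block = reverse_complement(
                chrom_seq[circ.acceptor_pos - arm - pad - 1 : circ.acceptor_pos + pad]
            )
        chrom = f"chr{self.config.n_chroms}"
        end = self._dump_cursor[chrom]
        start = end - (len(donor_block) + gap + len(acceptor_block)) + 1
        self._write(chrom, start, donor_block)
        self._write(chrom, start + len(donor_block) + gap, acceptor_block)
        self._dump_cursor[chrom] = start - 101
        entry = self.truth["events"][self.circs[event_index].event_id]
        entry["multiple_hits"] = True
        entry["retained"] = False

    def plant_rcs(
        self,
        event_index: int,
        n_across: int = 0,
        n_within_up: int = 0,
        n_within_down: int = 0,
        length: int = 60,
        identity: float = 1.0,
        subthreshold: bool = False,
    ) -> None:
        """Plant reverse-complement pairs in the event's flanks.

        ``subthreshold`` marks plants expected to be rejected by the RCS
        retention rule (they do not enter the truth counts).
        """
        eid = self.circs[event_index].event_id
        entry = self.truth["events"][eid]
        # upstream members in order, downstream members reversed: the pair
        # diagonals then cross, so no single (non-crossing) local alignment
        # can chain two pairs into one hit
        across_segs = [self._random_seq(length) for _ in range(n_across)]
        for s in across_segs:
            self._write_flank(event_index, "up", s)
        for s in reversed(across_segs):
            self._write_flank(event_index, "down", reverse_complement(_degrade(s, identity)))
        if not subthreshold:
            entry["rcs_across"] += n_across
        for which, count in (("up", n_within_up), ("down", n_within_down)):
            for _ in range(count):
                s = self._random_seq(length)
                self._write_flank(event_index, which, s)
                self._write_flank(event_index, which, reverse_complement(_degrade(s, identity)))
                if not subthreshold:
                    entry["rcs_within"] += 1
        if subthreshold:
            sub = self.truth["subthreshold_rcs"].setdefault(eid, 0)
            self.truth["subthreshold_rcs"][eid] = sub + n_across + n_within_up + n_within_down

    # -- miRNAs ---------------------------------------------------------

    def make_mirnas(self) -> None:
        """Draw miRNA sequences whose seeds are absent from every circle.

        Seed reverse complements must not occur in any (unplanted) extended
        circle sequence nor inside any other miRNA's site sequence, so that
        scanner hits exist only where sites are planted.
        """
        cfg = self.config
        circles = []
        for i in range(len(self.circs)):
            seq = self.circle(i).sequence
            circles.append(seq + seq[:30])
        accepted: list[str] = []
        while len(accepted) < cfg.n_mirnas:
            m = self._random_seq(int(self.rng.integers(cfg.mirna_len[0], cfg.mirna_len[1] + 1)))
            seed_rc = reverse_complement(m[SEED_START - 1 : SEED_END])
            if any(seed_rc in c for c in circles):
                continue
            if any(
                seed_rc in reverse_complement(other)
                or reverse_complement(other[SEED_START - 1 : SEED_END]) in reverse_complement(m)
                for other in accepted
            ):
                continue
            accepted.append(m)
        for i, m in enumerate(accepted, 1):
            self.mirnas.add(f"miR-{i}", m)

    def plant_mirna_site(
        self,
        event_index: int,
        mirna_id: str,
        site_type: str = "perfect",
        position: int | None = None,
    ) -> None:
        """Write a binding site for ``mirna_id`` into the event's circle.

        ``position`` is the 1-based circle position of the site start; the
        default places the site mid-circle (or across the junction for
        ``junction_spanning``).  ``seed_only`` keeps the seed pairing but
        replaces every non-seed site base by the miRNA's own base at the
        paired position, which can neither Watson-Crick nor wobble pair.
        """
        if site_type not in ("perfect", "seed_only", "junction_spanning"):
            raise ValueError(f"unknown site type {site_type!r}")
        m = self.mirnas[mirna_id]
        M = len(m)
        site = list(reverse_complement(m))
        if site_type == "seed_only":
            for idx in range(M):
                mirna_pos = M - idx
                if not (SEED_START <= mirna_pos <= SEED_END):
                    site[idx] = m[mirna_pos - 1]
        site_seq = "".join(site)
        circle = self.circle(event_index)
        L = len(circle)
        if position is None:
            position = L - M // 2 if site_type == "junction_spanning" else L // 2
        circ = self.circs[event_index]
        written: list[int] = []
        for offset, ch in enumerate(site_seq):
            p = (position - 1 + offset) % L + 1
            g = circle_position_to_genomic(circle, p)
            base = ch if circ.strand == "+" else reverse_complement(ch)
            self._chroms[circ.chrom][g - 1] = base
            written.append(g)
        lo, hi = min(written), max(written)
        self._plants.append((circ.chrom, lo, hi))
        spans = position + M - 1 > L
        self.truth["events"][circ.event_id]["sites"].append(
            {
                "mirna_id": mirna_id,
                "start": position,
                "end": (position + M - 2) % L + 1,
                "type": site_type,
                "spans_junction": spans,
                "clip": False,
                "passes_filter": site_type != "seed_only",
            }
        )

    def add_clip_for_site(self, event_index: int, site_index: int) -> None:
        """Emit a CLIP region covering a planted site's genomic span."""
        circ = self.circs[event_index]
        entry = self.truth["events"][circ.event_id]["sites"][site_index]
        circle = self.circle(event_index)
        start, end = entry["start"], entry["end"]
        if start <= end:
            positions = [start, end]
        else:
            positions = [start, len(circle)]
        coords = [circle_position_to_genomic(circle, p) for p in positions]
        lo, hi = min(coords), max(coords)
        self.clip_regions.append((circ.chrom, lo, hi, circ.strand))
        entry["clip"] = True

    def add_mimr(self, mirna_id: str, gene_id: str, label: str) -> None:
        self.mimr_rows.append((mirna_id, gene_id, label))
        self.truth["mimr"].append([mirna_id, gene_id, label])

    # -- bundle output ---------------------------------------------------

    def write_bundle(self, out_dir) -> Path:
        """Write genome.fa, annotation.gtf, circ.tsv, mirna.fa, evidence
        tables, clip_regions.tsv and truth.json; byte-deterministic."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "genome.fa", "w") as fh:
            for name in sorted(self._chroms):
                fh.write(f">{name}\n")
                seq = "".join(self._chroms[name])
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        with open(out / "annotation.gtf", "w") as fh:
            for tx in self.transcripts:
                for n, (s, e) in enumerate(tx.exons, 1):
                    attrs = (
                        f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
                        f'gene_name "{tx.gene_name}"; exon_number "{n}";'
                    )
                    fh.write(
                        f"{tx.chrom}\ttoy\texon\t{s}\t{e}\t.\t{tx.strand}\t.\t{attrs}\n"
                    )
        with open(out / "circ.tsv", "w") as fh:
            for c in self.circs:
                lo, hi = sorted((c.donor_pos, c.acceptor_pos))
                fh.write(f"{c.chrom}\t{lo}\t{hi}\t{c.strand}\n")
        with open(out / "mirna.fa", "w") as fh:
            for name, seq in self.mirnas.items():
                fh.write(f">{name}\n{seq}\n")
        for label in ("predicted", "validated", "clip"):
            with open(out / f"mimr_{label}.tsv", "w") as fh:
                fh.write("mirna_id\tgene_id\n")
                for mirna, gene, l in self.mimr_rows:
                    if l == label:
                        fh.write(f"{mirna}\t{gene}\n")
        with open(out / "clip_regions.tsv", "w") as fh:
            for chrom, s, e, strand in self.clip_regions:
                fh.write(f"{chrom}\t{s}\t{e}\t{strand}\n")
        with open(out / "truth.json", "w") as fh:
            json.dump(
                {"config": asdict(self.config), **self.truth},
                fh,
                indent=1,
                sort_keys=True,
            )
            fh.write("\n")
        return out


# ---------------------------------------------------------------------------
# Canonical builders


def make_basic_fixture(seed: int = 1, **overrides) -> ToyFixture:
    """Clean fixture: genes and circles only, nothing planted."""
    return ToyFixture(FixtureConfig(seed=seed, **overrides))


N_DECOY_MIRNAS = 37  # pads the co-regulation universe to 40 miRNAs


def make_acceptance_fixture(seed: int = 1) -> ToyFixture:
    """The full planted-truth study fixture: 20 circRNAs.

    Events 0-1: co-linear duplications; event 2: duplication detectable
    only at 9-mer seeding; events 3-5: multi-hit loci; events 6-9: RCS
    plants including sub-threshold negatives (length 40; identity 75%);
    events 10-13: miRNA sites (perfect + CLIP, junction-spanning,
    seed-only, double site); events 14-19: clean.  Evidence tables cover
    all four category combinations and pad the miRNA universe with decoys
    so the co-regulation test has resolution.
    """
    fx = ToyFixture(FixtureConfig(seed=seed, n_genes=20, n_chroms=2))
    fx.make_mirnas()
    fx.plant_duplication(0)
    fx.plant_duplication(1)
    fx.plant_duplication(2, sensitive_only=True)
    for i in (3, 4, 5):
        fx.plant_multihit(i)
    fx.plant_rcs(6, n_across=2, n_within_up=1)
    fx.plant_rcs(7, n_across=5, n_within_up=2, n_within_down=2)
    fx.plant_rcs(8, n_across=1, length=40, subthreshold=True)
    fx.plant_rcs(8, n_across=1, length=60, identity=0.75, subthreshold=True)
    fx.plant_rcs(9, n_within_down=1)
    fx.plant_mirna_site(10, "miR-1", "perfect")
    fx.add_clip_for_site(10, 0)
    fx.plant_mirna_site(11, "miR-2", "junction_spanning")
    fx.plant_mirna_site(12, "miR-3", "seed_only")
    fx.plant_mirna_site(13, "miR-1", "perfect", position=40)
    fx.plant_mirna_site(13, "miR-1", "perfect", position=140)
    fx.add_mimr("miR-1", "TG01", "validated")
    fx.add_mimr("miR-1", "TG01", "predicted")
    fx.add_mimr("miR-1", "TG02", "predicted")
    fx.add_mimr("miR-2", "TG03", "validated")
    fx.add_mimr("miR-2", "TG04", "predicted")
    fx.add_mimr("miR-3", "TG05", "predicted")
    for i in range(1, N_DECOY_MIRNAS + 1):
        fx.add_mimr(f"decoy-miR-{i:02d}", f"DG{i:02d}", "predicted")
    return fx
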