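"""End-to-end orchestration: bundle loading, per-event screening, axes.

The stages mirror the command surface: (1) assemble/validate a reference
bundle, (2) screen BSJs (boundary check, alignment ambiguity, RCS), (3)
predict miRNA sites and build the filtered circRNA-miRNA-mRNA network,
(4) export the network.  Per-event work is independent, so it can be
farmed out to worker processes; results are gathered and sorted by event
id, which makes parallel runs byte-identical to serial ones.
"""

from __future__ import annotations

import concurrent.futures
import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from .alignment import DEFAULT_SCORING, ReferenceIndex, ScoringScheme
from .ambiguity import AmbiguityVerdict, check_ambiguity
from .junctions import BsjCheckResult, CircleSequence, build_circle_sequence, build_junction_concat, check_boundaries
from .network import (
    Axis,
    CoRegulation,
    coregulation_table,
    filter_axes,
    join_axes,
    load_mimr_tables,
    mirna_universe,
    write_outputs,
)
from .rcs import (
    DEFAULT_FLANK,
    DEFAULT_THRESHOLDS,
    RCSSummary,
    RCSThresholds,
    extract_flanks,
    find_rcs_across,
    find_rcs_within,
    summarize_rcs,
)
from .reference import (
    CircJunction,
    GeneAnnotation,
    GenomeRef,
    MiRNARegistry,
    read_annotation_gtf,
    read_circ_junctions,
    read_genome_fasta,
    read_mirna_fasta,
)
from .targeting import (
    DEFAULT_OVERHANG,
    ENERGY_THRESHOLD,
    SCORE_THRESHOLD,
    CircMiInteraction,
    annotate_clip_support,
    collapse_to_interactions,
    filter_sites,
    load_clip_regions,
    scan_sites_builtin,
)

REQUIRED_BUNDLE_FILES = ("genome.fa", "annotation.gtf", "mirna.fa")
OPTIONAL_BUNDLE_FILES = (
    "mimr_predicted.tsv",
    "mimr_validated.tsv",
    "mimr_clip.tsv",
    "clip_regions.tsv",
    "circ.tsv",
    "truth.json",
)


@dataclass(frozen=True)
class RunConfig:
    """All tunable thresholds of a run; recorded verbatim in the manifest."""

    dist: int = DEFAULT_FLANK
    miranda_sc: float = SCORE_THRESHOLD
    energy: float = ENERGY_THRESHOLD
    rcs_thresholds: RCSThresholds = DEFAULT_THRESHOLDS
    fdr_alpha: float = 0.05
    overhang: int = DEFAULT_OVERHANG
    check_ambiguity: bool = True
    check_rcs: bool = True
    workers: int = 1
    coord_shift: int = 0
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class ReferenceBundle:
    root: Path
    genome: GenomeRef
    annotation: GeneAnnotation
    mirnas: MiRNARegistry
    mimr_paths: list[tuple[str, str]]  # (path, label)
    clip_regions: list[tuple[str, int, int, str]]

    @classmethod
    def from_dir(cls, path) -> "ReferenceBundle":
        root = Path(path)
        for name in REQUIRED_BUNDLE_FILES:
            if not (root / name).exists():
                raise FileNotFoundError(f"bundle {root} is missing required file {name}")
        mimr = []
        for label in ("predicted", "validated", "clip"):
            p = root / f"mimr_{label}.tsv"
            if p.exists():
                mimr.append((str(p), label))
        clip_path = root / "clip_regions.tsv"
        clip = load_clip_regions(clip_path) if clip_path.exists() else []
        return cls(
            root=root,
            genome=read_genome_fasta(root / "genome.fa"),
            annotation=read_annotation_gtf(root / "annotation.gtf"),
            mirnas=read_mirna_fasta(root / "mirna.fa"),
            mimr_paths=mimr,
            clip_regions=clip,
        )


def write_bundle_manifest(bundle_dir) -> Path:
    """Checksum manifest of every bundle file (reproducibility record)."""
    root = Path(bundle_dir)
    entries = {}
    for name in sorted(os.listdir(root)):
        p = root / name
        if p.is_file() and name != "MANIFEST.json":
            entries[name] = hashlib.sha256(p.read_bytes()).hexdigest()
    out = root / "MANIFEST.json"
    with open(out, "w") as fh:
        json.dump(entries, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return out


def write_run_manifest(out_dir, config: RunConfig, input_paths: list) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "inputs": {
            str(p): hashlib.sha256(Path(p).read_bytes()).hexdigest()
            for p in sorted(str(x) for x in input_paths)
            if Path(p).is_file()
        },
    }
    path = out_dir / "run_manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return path


# ---------------------------------------------------------------------------
# Stage 2: per-event screening


@dataclass
class EventScreen:
    event_id: str
    check: BsjCheckResult
    circle: CircleSequence | None = None
    verdict: AmbiguityVerdict | None = None
    rcs: RCSSummary | None = None


# worker globals inherited over fork by the process pool
_WORKER: dict = {}


def _screen_one(circ: CircJunction) -> EventScreen:
    bundle: ReferenceBundle = _WORKER["bundle"]
    config: RunConfig = _WORKER["config"]
    reference: ReferenceIndex = _WORKER["reference"]
    check = check_boundaries(circ, bundle.annotation)
    screen = EventScreen(event_id=circ.event_id, check=check)
    if check.passed:
        circle = build_circle_sequence(circ, check, bundle.annotation, bundle.genome)
        screen.circle = circle
        if config.check_ambiguity:
            concat = build_junction_concat(circle)
            screen.verdict = check_ambiguity(concat, circle, reference)
    if config.check_rcs:
        pair = extract_flanks(circ, bundle.genome, n=config.dist)
        across = find_rcs_across(pair, thresholds=config.rcs_thresholds)
        w_up = find_rcs_within(pair.upstream, "within_upstream", thresholds=config.rcs_thresholds)
        w_down = find_rcs_within(pair.downstream, "within_downstream", thresholds=config.rcs_thresholds)
        screen.rcs = summarize_rcs(circ.event_id, across, w_up, w_down)
    return screen


def screen_events(
    bundle: ReferenceBundle, circs: list[CircJunction], config: RunConfig
) -> dict[str, EventScreen]:
    """Run boundary/ambiguity/RCS screening for every event.

    With ``config.workers > 1`` events are screened in forked worker
    processes; the gathered results are keyed (hence ordered) by event_id,
    so the output is identical to a serial run.
    """
    _WORKER["bundle"] = bundle
    _WORKER["config"] = config
    _WORKER["reference"] = ReferenceIndex(bundle.genome, bundle.annotation)
    if config.workers > 1 and len(circs) > 1:
        ctx = concurrent.futures.ProcessPoolExecutor(
            max_workers=config.workers,
        )
        with ctx as pool:
            results = list(pool.map(_screen_one, circs))
    else:
        results = [_screen_one(c) for c in circs]
    return {s.event_id: s for s in sorted(results, key=lambda s: s.event_id)}


# ---------------------------------------------------------------------------
# Stage 3: interactions and network


@dataclass
class NetworkResult:
    interactions: list[CircMiInteraction]
    axes_all: list[Axis]
    axes_retained: list[Axis]
    coregs: dict[tuple[str, str], CoRegulation]


def build_network(
    bundle: ReferenceBundle,
    screens: dict[str, EventScreen],
    config: RunConfig,
    external_sites=None,
) -> NetworkResult:
    """Scan miRNA sites on every retained circle and build filtered axes.

    ``external_sites`` may carry pre-computed binding sites (for example
    parsed miRanda output keyed by event_id); they replace the built-in
    scanner but flow through the same filtering and collapsing.
    """
    all_sites = []
    for eid in sorted(screens):
        screen = screens[eid]
        if screen.circle is None:
            continue
        if config.check_ambiguity and screen.verdict is not None and not screen.verdict.retained:
            continue
        if external_sites is not None:
            sites = [s for s in external_sites if s.event_id == eid]
        else:
            sites = []
            for mirna_id, seq in bundle.mirnas.items():
                sites.extend(
                    scan_sites_builtin(screen.circle, mirna_id, seq, overhang=config.overhang)
                )
        sites = filter_sites(sites, config.miranda_sc, config.energy)
        if bundle.clip_regions:
            sites = annotate_clip_support(sites, bundle.clip_regions, screen.circle)
        all_sites.extend(sites)
    interactions = collapse_to_interactions(all_sites)
    mi_mr = load_mimr_tables(bundle.mimr_paths)
    axes = join_axes(interactions, mi_mr)
    universe = mirna_universe(bundle.mirnas, mi_mr)
    coregs = coregulation_table(axes, interactions, mi_mr, universe)
    retained = filter_axes(axes, coregs, alpha=config.fdr_alpha)
    return NetworkResult(
        interactions=interactions,
        axes_all=axes,
        axes_retained=retained,
        coregs=coregs,
    )


def run_pipeline(
    bundle: ReferenceBundle,
    circs: list[CircJunction],
    config: RunConfig,
    out_dir,
) -> tuple[Path, Path]:
    """Full screening + network run; writes summary_list and all_interactions."""
    screens = screen_events(bundle, circs, config)
    net = build_network(bundle, screens, config)
    return write_outputs(
        events=circs,
        checks={e: s.check for e, s in screens.items()},
        verdicts={e: s.verdict for e, s in screens.items() if s.verdict is not None},
        rcs_summaries={e: s.rcs for e, s in screens.items() if s.rcs is not None},
        interactions=net.interactions,
        axes=net.axes_retained,
        coregs=net.coregs,
        out_dir=out_dir,
    )
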