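"""circRNA-miRNA-mRNA network construction.

circRNA-miRNA interactions are joined with miRNA-mRNA evidence tables on
the shared miRNA to give ternary axes.  Each axis is tiered by experimental
support (category 1: both edges experimentally supported, 2: exactly one,
3: neither) and each distinct circRNA-mRNA pair is tested for miRNA
co-regulation with a hypergeometric tail probability

    P = sum_{i=s}^{min(t,c)} C(t,i) C(N-t, c-i) / C(N,c)

where N is the miRNA universe, t and c the pair's miRNA degrees and s the
shared-miRNA count.  P values are Benjamini-Hochberg adjusted across all
pairs and axes are retained at FDR < 0.05 (strict).
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .targeting import CircMiInteraction

FDR_ALPHA = 0.05


@dataclass(frozen=True)
class MiMrInteraction:
    mirna_id: str
    gene_id: str
    sources: frozenset[str]  # subset of {predicted, validated, clip}

    def __post_init__(self):
        if not self.sources:
            raise ValueError("sources must be non-empty")


@dataclass(frozen=True)
class CoRegulation:
    event_id: str
    gene_id: str
    n_universe: int
    t: int  # miRNAs targeting the mRNA
    c: int  # miRNAs targeting the circRNA
    s: int  # miRNAs targeting both
    p_value: float
    fdr: float = float("nan")


@dataclass(frozen=True)
class Axis:
    """One circRNA-miRNA-mRNA triple with its evidence tier."""

    event_id: str
    mirna_id: str
    gene_id: str
    circ_mi: CircMiInteraction
    mi_mr: MiMrInteraction
    category: int


VALID_SOURCES = {"predicted", "validated", "clip"}


def load_mimr_tables(paths_with_labels: list[tuple[str, str]]) -> list[MiMrInteraction]:
    """Load labelled miRNA-mRNA TSVs; duplicate pairs union their sources.

    Each file needs ``mirna_id`` and ``gene_id`` columns (extra columns are
    ignored); its label is one of predicted / validated / clip.
    """
    merged: dict[tuple[str, str], set[str]] = {}
    for path, label in paths_with_labels:
        if label not in VALID_SOURCES:
            raise ValueError(f"unknown evidence label {label!r}")
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = {"mirna_id", "gene_id"} - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for mirna, gene in zip(df["mirna_id"], df["gene_id"]):
            merged.setdefault((mirna, gene), set()).add(label)
    return [
        MiMrInteraction(m, g, frozenset(srcs))
        for (m, g), srcs in sorted(merged.items())
    ]


def categorize_axis(circ_mi: CircMiInteraction, mi_mr: MiMrInteraction) -> int:
    """Evidence tier: 1 = both edges experimental, 2 = exactly one, 3 = neither.

    A circRNA-miRNA edge is experimental when CLIP-supported; a miRNA-mRNA
    edge when any of its sources is validated or clip.
    """
    circ_exp = circ_mi.clip_supported
    mr_exp = bool(mi_mr.sources & {"validated", "clip"})
    if circ_exp and mr_exp:
        return 1
    if circ_exp or mr_exp:
        return 2
    return 3


def join_axes(
    circ_mi: list[CircMiInteraction], mi_mr: list[MiMrInteraction]
) -> list[Axis]:
    """One axis per (circRNA, miRNA, gene) sharing the miRNA."""
    by_mirna: dict[str, list[MiMrInteraction]] = {}
    for edge in mi_mr:
        by_mirna.setdefault(edge.mirna_id, []).append(edge)
    axes = []
    for ci in circ_mi:
        for edge in by_mirna.get(ci.mirna_id, ()):
            axes.append(
                Axis(
                    event_id=ci.event_id,
                    mirna_id=ci.mirna_id,
                    gene_id=edge.gene_id,
                    circ_mi=ci,
                    mi_mr=edge,
                    category=categorize_axis(ci, edge),
                )
            )
    axes.sort(key=lambda a: (a.event_id, a.mirna_id, a.gene_id))
    return axes


def coregulation_pvalue(n_universe: int, t: int, c: int, s: int) -> float:
    """Hypergeometric tail P(X >= s) for shared miRNA targeting."""
    if not (0 <= s <= min(t, c) <= n_universe and t <= n_universe and c <= n_universe):
        raise ValueError(f"invalid hypergeometric parameters N={n_universe} t={t} c={c} s={s}")
    if s == 0:
        return 1.0
    return float(hypergeom.sf(s - 1, n_universe, t, c))


def bh_adjust(p_values) -> list[float]:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    p = list(p_values)
    if not p:
        return []
    return list(multipletests(p, method="fdr_bh")[1])


def mirna_universe(
    scanned_mirnas, mi_mr: list[MiMrInteraction]
) -> set[str]:
    """miRNAs capable of generating evidence on either axis.

    The union of the registry entries scanned against circRNAs and the
    miRNAs appearing in the loaded miRNA-mRNA tables.
    """
    return set(scanned_mirnas) | {e.mirna_id for e in mi_mr}


def coregulation_table(
    axes: list[Axis],
    circ_mi: list[CircMiInteraction],
    mi_mr: list[MiMrInteraction],
    universe: set[str],
) -> dict[tuple[str, str], CoRegulation]:
    """Hypergeometric test for every distinct (circRNA, gene) pair in the
    axes, FDR-adjusted once across all pairs."""
    mirnas_per_circ: dict[str, set[str]] = {}
    for ci in circ_mi:
        mirnas_per_circ.setdefault(ci.event_id, set()).add(ci.mirna_id)
    mirnas_per_gene: dict[str, set[str]] = {}
    for edge in mi_mr:
        mirnas_per_gene.setdefault(edge.gene_id, set()).add(edge.mirna_id)
    pairs = sorted({(a.event_id, a.gene_id) for a in axes})
    n = len(universe)
    raw: list[CoRegulation] = []
    for event_id, gene_id in pairs:
        c_set = mirnas_per_circ.get(event_id, set()) & universe
        t_set = mirnas_per_gene.get(gene_id, set()) & universe
        s = len(c_set & t_set)
        p = coregulation_pvalue(n, len(t_set), len(c_set), s)
        raw.append(CoRegulation(event_id, gene_id, n, len(t_set), len(c_set), s, p))
    fdrs = bh_adjust([r.p_value for r in raw])
    return {
        (r.event_id, r.gene_id): CoRegulation(
            r.event_id, r.gene_id, r.n_universe, r.t, r.c, r.s, r.p_value, fdr
        )
        for r, fdr in zip(raw, fdrs)
    }


def filter_axes(
    axes: list[Axis],
    coregs: dict[tuple[str, str], CoRegulation],
    alpha: float = FDR_ALPHA,
) -> list[Axis]:
    """Keep axes whose circRNA-mRNA pair is co-regulated at FDR < alpha."""
    out = []
    for a in axes:
        key = (a.event_id, a.gene_id)
        if key not in coregs:
            raise KeyError(f"no co-regulation record for pair {key}")
        if coregs[key].fdr < alpha:
            out.append(a)
    return out


# ---------------------------------------------------------------------------
# Outputs


def write_outputs(
    events,
    checks: dict,
    verdicts: dict,
    rcs_summaries: dict,
    interactions: list[CircMiInteraction],
    axes: list[Axis],
    coregs: dict[tuple[str, str], CoRegulation],
    out_dir,
) -> tuple[Path, Path]:
    """Write summary_list.tsv (one row per input event) and
    all_interactions.tsv (one row per retained axis).

    Optional stages that did not run contribute "NA" columns.  Output is
    deterministic: rows sorted by event id (and miRNA/gene for axes).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_mirnas: dict[str, int] = {}
    for ci in interactions:
        n_mirnas[ci.event_id] = n_mirnas.get(ci.event_id, 0) + 1
    n_axes: dict[str, int] = {}
    for a in axes:
        n_axes[a.event_id] = n_axes.get(a.event_id, 0) + 1

    rows = []
    for circ in sorted(events, key=lambda c: c.event_id):
        eid = circ.event_id
        check = checks.get(eid)
        verdict = verdicts.get(eid)
        rcs = rcs_summaries.get(eid)
        rows.append(
            {
                "event_id": eid,
                "chrom": circ.chrom,
                "donor": circ.donor_pos,
                "acceptor": circ.acceptor_pos,
                "strand": circ.strand,
                "boundary_pass": "NA" if check is None else ("yes" if check.passed else "no"),
                "boundary_reason": "NA" if check is None else (check.reason or "-"),
                "colinear_explanation": "NA" if verdict is None else ("yes" if verdict.alt_colinear else "no"),
                "multiple_hits": "NA" if verdict is None else ("yes" if verdict.multiple_hits else "no"),
                "retained": "NA" if verdict is None else ("yes" if verdict.retained else "no"),
                "RCS_across": "NA" if rcs is None else rcs.rcs_across,
                "RCS_within": "NA" if rcs is None else rcs.rcs_within,
                "RCS_delta": "NA" if rcs is None else rcs.delta,
                "n_mirnas": n_mirnas.get(eid, 0),
                "n_axes_retained": n_axes.get(eid, 0),
            }
        )
    summary_path = out_dir / "summary_list.tsv"
    pd.DataFrame(rows).to_csv(summary_path, sep="\t", index=False)

    axis_rows = []
    for a in axes:
        co = coregs[(a.event_id, a.gene_id)]
        axis_rows.append(
            {
                "event_id": a.event_id,
                "mirna_id": a.mirna_id,
                "gene_id": a.gene_id,
                "n_sites": a.circ_mi.n_sites,
                "max_score": a.circ_mi.max_score,
                "spans_junction": "yes" if a.circ_mi.any_spans_junction else "no",
                "clip_supported": "yes" if a.circ_mi.clip_supported else "no",
                "mi_mr_sources": ",".join(sorted(a.mi_mr.sources)),
                "category": a.category,
                "coregulation_p": co.p_value,
                "coregulation_fdr": co.fdr,
            }
        )
    columns = [
        "event_id", "mirna_id", "gene_id", "n_sites", "max_score", "spans_junction",
        "clip_supported", "mi_mr_sources", "category", "coregulation_p", "coregulation_fdr",
    ]
    interactions_path = out_dir / "all_interactions.tsv"
    pd.DataFrame(axis_rows, columns=columns).to_csv(interactions_path, sep="\t", index=False)
    return summary_path, interactions_path


def export_cytoscape(axes: list[Axis], path) -> None:
    """Write the network as XGMML (Cytoscape File -> Import -> Network).

    Nodes are typed circRNA / miRNA / mRNA; edges carry the evidence
    category and, for circRNA-miRNA edges, the best site score.
    """
    graph = ET.Element(
        "graph",
        {
            "label": "circRNA-miRNA-mRNA network",
            "directed": "1",
            "xmlns": "http://www.cs.rpi.edu/XGMML",
        },
    )
    node_ids: dict[str, int] = {}

    def add_node(label: str, kind: str) -> int:
        if label not in node_ids:
            nid = len(node_ids) + 1
            node_ids[label] = nid
            node = ET.SubElement(graph, "node", {"id": str(nid), "label": label})
            ET.SubElement(node, "att", {"name": "type", "type": "string", "value": kind})
        return node_ids[label]

    seen_edges: set[tuple[int, int]] = set()

    def add_edge(src: int, dst: int, attrs: dict[str, str]) -> None:
        if (src, dst) in seen_edges:
            return
        seen_edges.add((src, dst))
        edge = ET.SubElement(graph, "edge", {"source": str(src), "target": str(dst)})
        for name, value in attrs.items():
            ET.SubElement(edge, "att", {"name": name, "type": "string", "value": value})

    for a in axes:
        circ = add_node(a.event_id, "circRNA")
        mir = add_node(a.mirna_id, "miRNA")
        gene = add_node(a.gene_id, "mRNA")
        add_edge(circ, mir, {"category": str(a.category), "score": repr(a.circ_mi.max_score)})
        add_edge(mir, gene, {"category": str(a.category),
                             "sources": ",".join(sorted(a.mi_mr.sources))})
    tree = ET.ElementTree(graph)
    ET.indent(tree)
    tree.write(path, encoding="unicode", xml_declaration=True)
    with open(path, "a") as fh:
        fh.write("\n")
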