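"""Gene-set enrichment of axis target genes.

For each curated gene list, the target genes of the retained axes are
tested against a protein-coding background with a one-tailed Fisher's exact
test on the 2x2 table (targets/non-targets x in-list/not-in-list) plus an
empirical resampling P value: |targets| genes are drawn without replacement
from the background n_draws times and

    empP = (1 + #{p_i > p_obs}) / (n_draws + 1)

where p_obs is the observed in-list proportion of the targets and p_i the
resampled proportions (strict inequality, so ties never count as more
extreme).  Fisher and empirical P values are each FDR-adjusted across gene
lists, as separate families.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import fisher_exact

from .network import bh_adjust

DEFAULT_N_DRAWS = 10_000


@dataclass(frozen=True)
class ResamplingPlan:
    n_draws: int = DEFAULT_N_DRAWS
    seed: int = 0

    def __post_init__(self):
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")


@dataclass(frozen=True)
class EnrichmentResult:
    """One gene list's enrichment against the background.

    Cells: a = targets in list, b = targets not in list, c = list genes not
    targeted, d = remaining background.  odds_ratio is the sample
    cross-product ratio a*d / (b*c) (inf when b*c = 0).
    """

    list_name: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    fisher_p: float
    emp_p: float = float("nan")
    fisher_fdr: float = float("nan")
    emp_fdr: float = float("nan")


def _clean_targets(targets, background: set[str]) -> set[str]:
    targets = set(targets)
    stray = targets - background
    if stray:
        warnings.warn(
            f"{len(stray)} target gene(s) absent from the background were dropped",
            stacklevel=3,
        )
    return targets & background


def fisher_enrichment(targets, gene_list, background, list_name: str = "") -> EnrichmentResult:
    """One-tailed (enrichment) Fisher's exact test of targets vs a gene list."""
    background = set(background)
    if not background:
        raise ValueError("empty background")
    targets = _clean_targets(targets, background)
    gene_list = set(gene_list) & background
    a = len(targets & gene_list)
    b = len(targets - gene_list)
    c = len(gene_list - targets)
    d = len(background) - a - b - c
    odds, p = fisher_exact([[a, b], [c, d]], alternative="greater")
    return EnrichmentResult(
        list_name=list_name, a=a, b=b, c=c, d=d,
        odds_ratio=float(odds), fisher_p=float(p),
    )


def empirical_enrichment(
    targets, gene_list, background, plan: ResamplingPlan
) -> float:
    """Empirical P of the observed in-list proportion under uniform draws.

    Drawing |targets| genes without replacement from the background and
    counting list members is a hypergeometric variate, so the null
    proportions are sampled directly from that distribution.
    """
    background = set(background)
    targets = _clean_targets(targets, background)
    gene_list = set(gene_list) & background
    if not targets:
        raise ValueError("no targets within the background")
    a_obs = len(targets & gene_list)
    rng = np.random.default_rng(plan.seed)
    n_good = len(gene_list)
    n_bad = len(background) - n_good
    draws = rng.hypergeometric(n_good, n_bad, len(targets), size=plan.n_draws)
    exceed = int(np.sum(draws > a_obs))  # p_i > p_obs <=> count > a_obs
    return (1 + exceed) / (plan.n_draws + 1)


def adjust_enrichment(results: list[EnrichmentResult]) -> list[EnrichmentResult]:
    """BH over the Fisher family and separately over the empirical family."""
    if not results:
        return []
    fisher_fdr = bh_adjust([r.fisher_p for r in results])
    have_emp = all(np.isfinite(r.emp_p) for r in results)
    emp_fdr = bh_adjust([r.emp_p for r in results]) if have_emp else [float("nan")] * len(results)
    return [
        replace(r, fisher_fdr=f, emp_fdr=e)
        for r, f, e in zip(results, fisher_fdr, emp_fdr)
    ]


def enrichment_table(
    targets,
    gene_lists: dict[str, set[str]],
    background,
    plan: ResamplingPlan | None = None,
) -> list[EnrichmentResult]:
    """Fisher + empirical enrichment over several gene lists, FDR-adjusted."""
    results = []
    for name in sorted(gene_lists):
        r = fisher_enrichment(targets, gene_lists[name], background, list_name=name)
        if plan is not None:
            # one independent substream per list, derived from the plan seed
            # (stable across processes, unlike the builtin str hash)
            digest = hashlib.sha256(f"{plan.seed}:{name}".encode()).digest()
            sub = ResamplingPlan(plan.n_draws, seed=int.from_bytes(digest[:4], "big") % (2**31))
            r = replace(r, emp_p=empirical_enrichment(targets, gene_lists[name], background, sub))
        results.append(r)
    return adjust_enrichment(results)


def write_enrichment(results: list[EnrichmentResult], path) -> None:
    cols = ["list_name", "a", "b", "c", "d", "odds_ratio",
            "fisher_p", "fisher_fdr", "emp_p", "emp_fdr"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in results:
            fh.write(
                "\t".join(
                    str(getattr(r, c)) for c in cols
                )
                + "\n"
            )
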