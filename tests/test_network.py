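import itertools
import math
import xml.etree.ElementTree as ET

import numpy as np
import pytest

from circaxis.network import (
    Axis,
    MiMrInteraction,
    bh_adjust,
    categorize_axis,
    coregulation_pvalue,
    coregulation_table,
    export_cytoscape,
    filter_axes,
    join_axes,
    load_mimr_tables,
    mirna_universe,
)
from circaxis.targeting import CircMiInteraction


def _ci(event="c1", mirna="miR-1", clip=False):
    return CircMiInteraction(event, mirna, 1, 170.0, False, clip)


def _mm(mirna="miR-1", gene="g1", sources=("predicted",)):
    return MiMrInteraction(mirna, gene, frozenset(sources))


class TestLoadTables:
    def test_union_of_sources(self, tmp_path):
        a = tmp_path / "p.tsv"
        a.write_text("mirna_id\tgene_id\nmiR-1\tg1\n")
        b = tmp_path / "v.tsv"
        b.write_text("mirna_id\tgene_id\textra\nmiR-1\tg1\tx\n")
        (rec,) = load_mimr_tables([(str(a), "predicted"), (str(b), "validated")])
        assert rec.sources == {"predicted", "validated"}

    def test_row_count(self, tmp_path):
        p = tmp_path / "p.tsv"
        rows = [f"m{i}\tg{j}" for i in range(3) for j in range(4)]
        p.write_text("mirna_id\tgene_id\n" + "\n".join(rows) + "\n")
        assert len(load_mimr_tables([(str(p), "predicted")])) == 12

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "p.tsv"
        p.write_text("mirna\tgene\nx\ty\n")
        with pytest.raises(ValueError, match="missing columns"):
            load_mimr_tables([(str(p), "predicted")])

    def test_empty_table_ok(self, tmp_path):
        p = tmp_path / "p.tsv"
        p.write_text("mirna_id\tgene_id\n")
        assert load_mimr_tables([(str(p), "predicted")]) == []


class TestJoin:
    def test_product_cardinality(self):
        circ_mi = [_ci("c1"), _ci("c2")]
        mi_mr = [_mm(gene=g) for g in ("g1", "g2", "g3")]
        assert len(join_axes(circ_mi, mi_mr)) == 6

    def test_disjoint_mirnas_empty(self):
        assert join_axes([_ci(mirna="miR-1")], [_mm(mirna="miR-2")]) == []

    def test_count_conservation_random(self):
        rng = np.random.default_rng(3)
        mirnas = [f"m{i}" for i in range(6)]
        circ_mi = [
            _ci(f"c{i}", rng.choice(mirnas)) for i in range(12)
        ]
        mi_mr = [_mm(rng.choice(mirnas), f"g{i}") for i in range(15)]
        axes = join_axes(circ_mi, mi_mr)
        # brute-force nested-loop oracle
        expected = sum(
            1 for ci in circ_mi for mm in mi_mr if ci.mirna_id == mm.mirna_id
        )
        assert len(axes) == expected


class TestCategories:
    @pytest.mark.parametrize(
        "clip,sources,category",
        [
            (True, {"validated"}, 1),
            (True, {"predicted"}, 2),
            (False, {"validated", "predicted"}, 2),
            (False, {"predicted"}, 3),
            (True, {"clip"}, 1),
        ],
    )
    def test_tiers(self, clip, sources, category):
        assert categorize_axis(_ci(clip=clip), _mm(sources=sources)) == category

    def test_partition_sums(self):
        combos = [
            (_ci("c1", clip=True), _mm(sources={"validated"})),
            (_ci("c2", clip=True), _mm(sources={"predicted"})),
            (_ci("c3", clip=False), _mm(sources={"validated"})),
            (_ci("c4", clip=False), _mm(sources={"predicted"})),
        ]
        cats = [categorize_axis(c, m) for c, m in combos]
        assert sorted(cats) == [1, 2, 2, 3]


def hypergeom_tail_enumeration(N, t, c, s):
    """Independent oracle: exact subset enumeration."""
    t_set = set(range(t))
    total = hits = 0
    for subset in itertools.combinations(range(N), c):
        total += 1
        if len(t_set & set(subset)) >= s:
            hits += 1
    return hits / total


class TestCoregulationPvalue:
    @pytest.mark.parametrize(
        "N,t,c,s,expected",
        [
            (10, 4, 5, 0, 1.0),
            (10, 4, 5, 4, 6 / 252),
            (10, 4, 5, 3, 66 / 252),
        ],
    )
    def test_known_values(self, N, t, c, s, expected):
        assert coregulation_pvalue(N, t, c, s) == pytest.approx(expected, rel=1e-12)

    def test_matches_enumeration_spot(self):
        for N, t, c, s in [(8, 3, 4, 2), (9, 5, 5, 3), (7, 2, 6, 1)]:
            assert coregulation_pvalue(N, t, c, s) == pytest.approx(
                hypergeom_tail_enumeration(N, t, c, s), rel=1e-9
            )

    def test_monotone_in_s(self):
        ps = [coregulation_pvalue(12, 6, 7, s) for s in range(0, 7)]
        assert ps[0] == 1.0
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            coregulation_pvalue(5, 6, 2, 1)
        with pytest.raises(ValueError):
            coregulation_pvalue(10, 4, 5, 5)


def bh_stepup_oracle(pvals):
    """Hand step-up: sort, q_i = p_i*m/i, monotonize from the top, cap at 1."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, pvals[i] * m / rank)
        q[i] = val
        prev = val
    return [min(1.0, v) for v in q]


class TestBH:
    def test_worked_example(self):
        got = bh_adjust([0.01, 0.02, 0.04, 0.8])
        assert got == pytest.approx([0.04, 0.04, 0.05333333, 0.8], rel=1e-6)

    def test_single_value_unchanged(self):
        assert bh_adjust([0.2]) == [pytest.approx(0.2)]

    def test_all_equal_unchanged(self):
        assert bh_adjust([0.3, 0.3, 0.3]) == pytest.approx([0.3, 0.3, 0.3])

    def test_matches_oracle_with_ties(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            m = int(rng.integers(1, 12))
            p = np.round(rng.random(m), 2).tolist()
            assert bh_adjust(p) == pytest.approx(bh_stepup_oracle(p), rel=1e-9)

    def test_output_dominates_input_and_order_invariance(self):
        rng = np.random.default_rng(23)
        p = rng.random(15).tolist()
        q = bh_adjust(p)
        assert all(b >= a for a, b in zip(p, q))
        perm = rng.permutation(15)
        q_perm = bh_adjust([p[i] for i in perm])
        assert q_perm == pytest.approx([q[i] for i in perm])


class TestFilterAxes:
    def _setup(self, universe_n=40):
        circ_mi = [_ci("c1", "miR-1")]
        mi_mr = [_mm("miR-1", "g1", {"validated"})]
        axes = join_axes(circ_mi, mi_mr)
        universe = {f"m{i}" for i in range(universe_n - 1)} | {"miR-1"}
        coregs = coregulation_table(axes, circ_mi, mi_mr, universe)
        return axes, coregs

    def test_small_universe_not_significant(self):
        axes, coregs = self._setup(universe_n=10)
        assert coregs[("c1", "g1")].p_value == pytest.approx(0.1)
        assert filter_axes(axes, coregs) == []

    def test_large_universe_significant(self):
        axes, coregs = self._setup(universe_n=40)
        assert coregs[("c1", "g1")].p_value == pytest.approx(1 / 40)
        assert filter_axes(axes, coregs) == axes

    def test_exact_alpha_dropped(self):
        axes, coregs = self._setup(universe_n=20)  # p = fdr = 0.05
        assert coregs[("c1", "g1")].fdr == pytest.approx(0.05)
        assert filter_axes(axes, coregs, alpha=0.05) == []

    def test_missing_record_rejected(self):
        axes, _ = self._setup()
        with pytest.raises(KeyError):
            filter_axes(axes, {})

    def test_universe_definition(self):
        scanned = ["miR-1", "miR-2"]
        tables = [_mm("miR-2"), _mm("miR-9")]
        assert mirna_universe(scanned, tables) == {"miR-1", "miR-2", "miR-9"}


class TestCytoscapeExport:
    def _axis(self, event="c1", mirna="miR-1", gene="g1"):
        return Axis(event, mirna, gene, _ci(event, mirna), _mm(mirna, gene), 3)

    def test_single_axis(self, tmp_path):
        p = tmp_path / "net.xgmml"
        export_cytoscape([self._axis()], p)
        root = ET.parse(p).getroot()
        ns = "{http://www.cs.rpi.edu/XGMML}"
        assert len(root.findall(f"{ns}node")) == 3
        assert len(root.findall(f"{ns}edge")) == 2

    def test_shared_mirna_dedup(self, tmp_path):
        p = tmp_path / "net.xgmml"
        export_cytoscape([self._axis(), self._axis(event="c2", gene="g2")], p)
        root = ET.parse(p).getroot()
        ns = "{http://www.cs.rpi.edu/XGMML}"
        assert len(root.findall(f"{ns}node")) == 5
        assert len(root.findall(f"{ns}edge")) == 4

    def test_empty_graph_valid(self, tmp_path):
        p = tmp_path / "net.xgmml"
        export_cytoscape([], p)
        root = ET.parse(p).getroot()
        assert root.tag.endswith("graph")
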