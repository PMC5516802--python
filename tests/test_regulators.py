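"""Regulator-network construction and pathway-fraction scoring."""

import networkx as nx
import numpy as np
import pytest

from mirscreen.regulators import (
    build_phospho_regulators,
    export_pathway_network,
    pathway_fractions,
)
from mirscreen.screens import PathwaySet

from conftest import make_discrete


def three_screens(states_per_line):
    return [make_discrete(s, cell_line=l)
            for s, l in zip(states_per_line, "ABC")]


class TestBuildRegulators:
    def test_two_line_support_makes_edge(self):
        # miRNA 0 up-regulates proteins 0 and 1 in lines A and B
        a = [[1, 1, 0], [0, 0, 0]]
        b = [[1, 1, 0], [0, 0, 0]]
        c = [[0, 0, 0], [0, 0, 0]]
        up, down = build_phospho_regulators(three_screens([a, b, c]),
                                            ["P000", "P001", "P002"])
        assert len(up.edges) == 2
        assert set(up.edges["n_lines_support"]) == {2}
        assert len(down.edges) == 0

    def test_single_target_mirna_excluded(self):
        a = [[1, 0, 0], [1, 1, 0]]
        b = [[1, 0, 0], [1, 1, 0]]
        c = [[0, 0, 0], [0, 0, 0]]
        up, _ = build_phospho_regulators(three_screens([a, b, c]),
                                         ["P000", "P001", "P002"])
        # miRNA 0 regulates only one protein -> dropped; miRNA 1 keeps both
        assert set(up.edges["mirna"]) == {"miR-001"}
        assert len(up.edges) == 2

    def test_conflicting_support_dropped_and_logged(self):
        a = [[1, 1, 1]]
        b = [[1, 1, 1]]
        c = [[0, 0, 0]]
        # protein 0 also down in two other "lines"
        d = [[-1, 0, 0]]
        e = [[-1, 0, 0]]
        up, down = build_phospho_regulators(
            three_screens([a, b, c]) + [make_discrete(d, cell_line="D"),
                                        make_discrete(e, cell_line="E")],
            ["P000", "P001", "P002"],
        )
        assert ("miR-000", "P000") in up.dropped_conflicts
        assert "P000" not in set(up.edges["protein"])
        up_pairs = set(zip(up.edges["mirna"], up.edges["protein"]))
        down_pairs = set(zip(down.edges["mirna"], down.edges["protein"]))
        assert not up_pairs & down_pairs

    def test_too_few_screens_rejected(self):
        with pytest.raises(ValueError, match="min_lines"):
            build_phospho_regulators([make_discrete([[1]])], ["P000"],
                                     min_lines=2)

    def test_filters_anti_monotone(self):
        rng = np.random.default_rng(0)
        screens = three_screens([rng.choice([-1, 0, 1], size=(30, 10),
                                            p=[0.2, 0.6, 0.2])
                                 for _ in range(3)])
        proteins = screens[0].protein_ids
        edges = {}
        for min_lines in (1, 2, 3):
            for min_targets in (1, 2, 3):
                up, down = build_phospho_regulators(
                    screens, proteins, min_lines=min_lines,
                    min_targets=min_targets)
                edges[(min_lines, min_targets)] = (
                    set(map(tuple, up.edges[["mirna", "protein"]].to_numpy()))
                    | set(map(tuple, down.edges[["mirna", "protein"]].to_numpy()))
                )
        for ml in (1, 2):
            for mt in (1, 2, 3):
                assert edges[(ml + 1, mt)] <= edges[(ml, mt)]
        for ml in (1, 2, 3):
            for mt in (1, 2):
                assert edges[(ml, mt + 1)] <= edges[(ml, mt)]

    def test_planted_regulators_recovered(self):
        from mirscreen.preprocess import discretize
        from mirscreen.screens import is_phospho
        from mirscreen.simulate import (
            SimulationConfig,
            simulate_secondary_screens,
        )

        perfect = 0
        for seed in range(8):
            sec = simulate_secondary_screens(SimulationConfig(seed=seed),
                                             flip_prob=0.05, seed=seed)
            discs = [discretize(s) for s in sec.screens]
            phospho = [p for p in sec.screens[0].protein_ids if is_phospho(p)]
            up, down = build_phospho_regulators(discs, phospho)
            est = set()
            for net in (up, down):
                est |= set(zip(net.edges["mirna"], net.edges["protein"],
                               net.edges["sign"]))
            truth = {(r.mirna, r.protein, r.sign)
                     for r in sec.regulators.itertuples()}
            perfect += truth <= est
        assert perfect >= 8 * 0.95 - 1e-9


class TestPathwayFractions:
    def test_half_regulated_is_included_exactly(self):
        d = make_discrete([[1, -1, 0, 0]])
        ps = PathwaySet("pw", frozenset(d.protein_ids))
        reg = pathway_fractions(d, [ps])
        row = reg.table.iloc[0]
        assert row["fraction"] == 0.5 and bool(row["included"])
        reg2 = pathway_fractions(d, [ps], threshold=0.51)
        assert not reg2.table.iloc[0]["included"]

    def test_all_zero_states_never_included(self):
        d = make_discrete(np.zeros((3, 4), dtype=int))
        ps = PathwaySet("pw", frozenset(d.protein_ids[:2]))
        reg = pathway_fractions(d, [ps])
        assert (reg.table["fraction"] == 0).all()
        assert not reg.table["included"].any()

    def test_unmeasured_pathway_warned_and_excluded(self):
        d = make_discrete([[1, 0]])
        ps = PathwaySet("ghost", frozenset({"NOT_MEASURED"}))
        with pytest.warns(UserWarning, match="no measured members"):
            reg = pathway_fractions(d, [ps])
        assert reg.table.empty

    def test_fraction_uses_measured_denominator(self):
        d = make_discrete([[1, 1, 0]])
        ps = PathwaySet("pw", frozenset({"P000", "P001", "UNSEEN1", "UNSEEN2"}))
        reg = pathway_fractions(d, [ps])
        assert reg.table.iloc[0]["fraction"] == 1.0  # 2 of 2 measured

    def test_invariant_to_protein_and_pathway_order(self, rng):
        states = rng.choice([-1, 0, 1], size=(10, 6))
        d = make_discrete(states)
        p1 = PathwaySet("a", frozenset(d.protein_ids[:4]))
        p2 = PathwaySet("b", frozenset(d.protein_ids[2:]))
        t1 = pathway_fractions(d, [p1, p2]).table
        d_shuffled = d.subset(proteins=list(reversed(d.protein_ids)))
        t2 = pathway_fractions(d_shuffled, [p2, p1]).table
        key = ["mirna", "pathway"]
        merged = t1.merge(t2, on=key, suffixes=("_1", "_2"))
        assert (merged["fraction_1"] == merged["fraction_2"]).all()

    def test_cell_cycle_cluster_dominates_cell_cycle_pathway(self):
        from mirscreen.preprocess import discretize, normalize
        from mirscreen.simulate import (
            SimulationConfig,
            default_pathways,
            simulate_primary_screen,
        )

        cfg = SimulationConfig(seed=4)
        screen, labels = simulate_primary_screen(cfg)
        controls = [m for m in screen.mirna_ids if m.startswith("NTC-")]
        norm = normalize(screen, controls, drop_controls=True)
        reg = pathway_fractions(discretize(norm), default_pathways())
        inc = reg.included()
        lab = dict(zip(norm.mirna_ids, labels[:cfg.n_mirna]))
        cc = inc[inc["pathway"] == "CellCycle"]["mirna"]
        assert len(cc) > 0
        share = np.mean([lab[m] == 2 for m in cc])
        assert share > 0.6  # the planted cell-cycle cluster dominates


class TestExport:
    def test_empty_regulation_gives_empty_graph(self):
        d = make_discrete(np.zeros((2, 3), dtype=int))
        ps = PathwaySet("pw", frozenset(d.protein_ids))
        g = export_pathway_network(pathway_fractions(d, [ps]))
        assert g.number_of_nodes() == 0 and g.number_of_edges() == 0

    def test_single_included_pair(self):
        d = make_discrete([[1, 1]])
        ps = PathwaySet("pw", frozenset(d.protein_ids))
        g = export_pathway_network(pathway_fractions(d, [ps]),
                                   {"miR-000": 2})
        assert g.number_of_nodes() == 2 and g.number_of_edges() == 1
        assert g["miR-000"]["pw"]["weight"] == 1.0
        assert g.nodes["miR-000"]["color"] == 2

    def test_graphml_round_trip_preserves_attributes(self, tmp_path):
        d = make_discrete([[1, 1], [0, 1]])
        ps = PathwaySet("pw", frozenset(d.protein_ids))
        g = export_pathway_network(pathway_fractions(d, [ps]), {"miR-000": 1})
        path = tmp_path / "pw.graphml"
        nx.write_graphml(g, path)
        back = nx.read_graphml(path)
        assert back.nodes["miR-000"]["size"] == 1.0
        assert back.nodes["miR-000"]["color"] == 1
        assert back["miR-000"]["pw"]["weight"] == 1.0
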