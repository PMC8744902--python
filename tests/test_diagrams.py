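"""Friend/follower diagram construction, coloring and export."""

import numpy as np
import networkx as nx
import pandas as pd
import pytest

import regomax as rx


@pytest.fixture(scope="module")
def groups6():
    # minimal group with the rows the color rule needs: U1,U2,D1,D2 plus T1,X1
    frame = pd.DataFrame(
        [
            dict(Kg=1, subgroup="t", subgroup_index=1, node_id="t1", protein_name="t1"),
            dict(Kg=2, subgroup="u", subgroup_index=1, node_id="u1", protein_name="u1"),
            dict(Kg=3, subgroup="u", subgroup_index=2, node_id="u2", protein_name="u2"),
            dict(Kg=4, subgroup="d", subgroup_index=1, node_id="d1", protein_name="d1"),
            dict(Kg=5, subgroup="d", subgroup_index=2, node_id="d2", protein_name="d2"),
            dict(Kg=6, subgroup="x", subgroup_index=1, node_id="x1", protein_name="x1"),
        ]
    )
    return rx.ProteinGroupTable(frame)


@pytest.fixture(scope="module")
def matrix6(groups6):
    rng = np.random.default_rng(12)
    g = rng.uniform(0.01, 0.2, size=(6, 6))
    np.fill_diagonal(g, 0.0)
    return g


class TestBuildDiagram:
    def test_levels_zero_only_top_nodes(self, matrix6, groups6):
        graph = rx.build_friend_follower_diagram(
            matrix6, groups6, ["U1", "U2", "D1", "D2", "X1"], levels=0)
        assert len(graph.nodes) == 5 and not graph.edges
        assert all(n.level == 0 and n.parent is None for n in graph.nodes)

    def test_friend_expansion_picks_largest_column_entries(self, groups6):
        # oracle: brute-force sort of the parent's column
        g = np.zeros((6, 6))
        g[:, 1] = [0.4, 0.0, 0.3, 0.2, 0.1, 0.05]  # column of U1 (position 1)
        graph = rx.build_friend_follower_diagram(
            g, groups6, ["U1"], mode="friend", branch=4, levels=1)
        picked = {e.dst for e in graph.edges}
        assert picked == {"T1", "U2", "D1", "D2"}  # 4 largest, self excluded
        assert all(e.src == "U1" and e.stage == "primary" for e in graph.edges)

    def test_follower_mode_uses_rows_and_reverses_arrows(self, groups6):
        g = np.zeros((6, 6))
        g[1, :] = [0.4, 0.0, 0.3, 0.2, 0.1, 0.05]
        graph = rx.build_friend_follower_diagram(
            g, groups6, ["U1"], mode="follower", branch=2, levels=1)
        assert {e.src for e in graph.edges} == {"T1", "U2"}
        assert all(e.dst == "U1" for e in graph.edges)

    def test_red_pair_links_excluded(self, matrix6, groups6):
        graph = rx.build_friend_follower_diagram(
            matrix6, groups6, ["X1", "U1"], mode="friend", levels=2)
        red = {"T1", "X1"}
        for e in graph.edges:
            assert not (e.src in red and e.dst in red)

    def test_strength_uses_modulus_but_keeps_sign(self, groups6):
        g = np.zeros((6, 6))
        g[:, 1] = [0.0, 0.0, -0.5, 0.1, 0.0, 0.0]
        graph = rx.build_friend_follower_diagram(
            g, groups6, ["U1"], branch=1, levels=1)
        assert graph.edges[0].dst == "U2"
        assert graph.edges[0].strength == -0.5

    def test_determinism_and_branch_bound(self, matrix6, groups6):
        tops = ["U1", "U2", "D1", "D2", "X1"]
        a = rx.build_friend_follower_diagram(matrix6, groups6, tops)
        b = rx.build_friend_follower_diagram(matrix6, groups6, tops)
        assert [vars(n) for n in a.nodes] == [vars(n) for n in b.nodes]
        assert [vars(e) for e in a.edges] == [vars(e) for e in b.edges]
        out_per_node = pd.Series([e.src for e in a.edges]).value_counts()
        assert (out_per_node <= 2 * 4).all()  # <= branch per expansion stage

    def test_unknown_top_label_rejected(self, matrix6, groups6):
        with pytest.raises(ValueError, match="U9"):
            rx.build_friend_follower_diagram(matrix6, groups6, ["U9"])


class TestColors:
    def test_rules(self, groups6):
        g_nd = np.zeros((6, 6))
        graph = rx.build_friend_follower_diagram(
            np.ones((6, 6)) - np.eye(6), groups6,
            ["U1", "U2", "D1", "D2", "X1"], levels=1)
        # make D2's extra follower comparisons deterministic
        g_nd[1, :] = 0.02  # U1 row
        g_nd[2, :] = 0.01  # U2 row
        g_nd[3, :] = 0.03  # D1 row
        g_nd[4, :] = 0.03  # D2 row: ties -> strict '>' fails -> second color
        rx.assign_subgroup_colors(graph, g_nd, groups6)
        colors = {n.label: n.color for n in graph.nodes}
        assert colors["T1"] == "red" and colors["X1"] == "red"
        assert colors["U1"] == "olive" and colors["U2"] == "green"
        assert colors["D1"] == "cyan" and colors["D2"] == "blue"

    def test_tie_falls_to_second_color_and_rule_instance(self, groups6):
        frame = groups6.frame.copy()
        frame.loc[len(frame)] = dict(Kg=7, subgroup="u", subgroup_index=3,
                                     node_id="u3", protein_name="u3")
        groups7 = rx.ProteinGroupTable(frame)
        g = np.ones((7, 7)) - np.eye(7)
        graph = rx.build_friend_follower_diagram(
            g, groups7, ["U1", "U2", "D1", "D2", "X1"], branch=6, levels=1)
        g_nd = np.zeros((7, 7))
        g_nd[1, 6] = 0.02
        g_nd[2, 6] = 0.01   # U3 follows U1 more strongly -> olive
        rx.assign_subgroup_colors(graph, g_nd, groups7)
        assert graph.node("U3").color == "olive"
        g_nd[2, 6] = 0.02   # exact tie -> green
        rx.assign_subgroup_colors(graph, g_nd, groups7)
        assert graph.node("U3").color == "green"

    def test_missing_leading_rows_rejected(self, matrix6):
        frame = pd.DataFrame(
            [dict(Kg=1, subgroup="x", subgroup_index=1, node_id="x1",
                  protein_name="x1"),
             dict(Kg=2, subgroup="x", subgroup_index=2, node_id="x2",
                  protein_name="x2")]
        )
        groups = rx.ProteinGroupTable(frame)
        graph = rx.build_friend_follower_diagram(
            np.ones((2, 2)) - np.eye(2), groups, ["X1"], levels=0)
        with pytest.raises(ValueError, match="U1"):
            rx.assign_subgroup_colors(graph, np.zeros((2, 2)), groups)


class TestExport:
    def test_dot_levels_zero(self, matrix6, groups6, tmp_path):
        graph = rx.build_friend_follower_diagram(
            matrix6, groups6, ["U1", "U2", "D1", "D2", "X1"], levels=0)
        p = tmp_path / "d.dot"
        rx.export_diagram(graph, p, format="dot")
        text = p.read_text()
        assert text.count("->") == 0
        assert sum(1 for l in text.splitlines() if "[level=" in l) == 5

    def test_graphml_round_trip(self, matrix6, groups6, tmp_path):
        graph = rx.build_friend_follower_diagram(
            matrix6, groups6, ["U1", "U2", "D1", "D2", "X1"], levels=2)
        rx.assign_subgroup_colors(graph, matrix6, groups6)
        p = tmp_path / "d.graphml"
        rx.export_diagram(graph, p, format="graphml")
        back = nx.read_graphml(p)
        assert sorted(back.nodes) == sorted(graph.labels)
        got = sorted((u, v, d["stage"]) for u, v, d in back.edges(data=True))
        want = sorted((e.src, e.dst, e.stage) for e in graph.edges)
        assert got == want

    def test_unsupported_format_rejected(self, matrix6, groups6, tmp_path):
        graph = rx.build_friend_follower_diagram(matrix6, groups6, ["U1"], levels=0)
        with pytest.raises(ValueError, match="unsupported"):
            rx.export_diagram(graph, tmp_path / "x.svg", format="svg")
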