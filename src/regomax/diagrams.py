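"""Friend/follower effective-network diagrams of a reduced matrix.

A matrix element g(a, b) is the strength of the link b -> a: a is a "friend"
of b and b a "follower" of a.  Starting from a handful of top nodes, the
diagram expands each node's few strongest friends (column entries) or
followers (row entries) for two levels, by modulus of the matrix element.
Links internal to the combined TGF-beta + X subgroup are excluded (they would
dominate), and nodes already placed only gain an edge, never a new position.
Subgroup colors encode which of the two leading up- (or down-) proteins a
node follows more strongly, always judged on the direct-plus-indirect matrix
Grr + Gqr(nd) whatever matrix the diagram itself was built from.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .network import ProteinGroupTable

__all__ = [
    "DiagramNode",
    "DiagramEdge",
    "DiagramGraph",
    "build_friend_follower_diagram",
    "assign_subgroup_colors",
    "export_diagram",
]

RED_SUBGROUPS = ("t", "x")


@dataclass
class DiagramNode:
    label: str               # U1 / D2 / X9 / T3
    position: int            # 0-based group position (Kg - 1)
    level: int
    parent: str | None
    color: str | None = None


@dataclass
class DiagramEdge:
    src: str
    dst: str
    stage: str               # primary (level-0 expansion) or secondary
    strength: float          # signed underlying matrix element


@dataclass
class DiagramGraph:
    mode: str                # friend | follower
    source_matrix: str       # GR | Grr_plus_Gqrnd
    nodes: list = field(default_factory=list)
    edges: list = field(default_factory=list)

    def node(self, label: str) -> DiagramNode:
        for n in self.nodes:
            if n.label == label:
                return n
        raise KeyError(label)

    @property
    def labels(self) -> list:
        return [n.label for n in self.nodes]


def _is_red(groups: ProteinGroupTable, position: int) -> bool:
    return groups.frame.iloc[position]["subgroup"] in RED_SUBGROUPS


def build_friend_follower_diagram(
    g: np.ndarray,
    groups: ProteinGroupTable,
    top_nodes,
    mode: str = "friend",
    branch: int = 4,
    levels: int = 2,
    source_matrix: str = "GR",
) -> DiagramGraph:
    """Expand the strongest friends/followers of the top nodes over ``levels``.

    ``top_nodes`` are subgroup labels (e.g. ``["U1", "U2", "D1", "D2", "X9"]``).
    Friends of a node are the ``branch`` largest entries (by modulus) of its
    column; followers, of its row.  Ties break by ascending Kg.  Pairs with
    both endpoints in the TGF-beta/X (red) group are skipped.
    """
    if mode not in ("friend", "follower"):
        raise ValueError(f"unknown mode {mode!r}")
    nr = len(groups)
    if g.shape != (nr, nr):
        raise ValueError("matrix size does not match group table")
    graph = DiagramGraph(mode=mode, source_matrix=source_matrix)
    placed: dict[str, DiagramNode] = {}
    for lbl in top_nodes:
        pos = groups.position_of_label(lbl)  # raises on unknown label
        node = DiagramNode(label=groups.label(pos), position=pos, level=0, parent=None)
        placed[node.label] = node
        graph.nodes.append(node)
    frontier = list(graph.nodes)
    for stage in range(1, levels + 1):
        stage_name = "primary" if stage == 1 else "secondary"
        next_frontier = []
        for parent in frontier:
            a = parent.position
            strengths = g[:, a] if mode == "friend" else g[a, :]
            order = np.lexsort((np.arange(nr), -np.abs(strengths)))
            picked = 0
            for b in order:
                b = int(b)
                if b == a:
                    continue
                if _is_red(groups, a) and _is_red(groups, b):
                    continue
                if picked >= branch:
                    break
                picked += 1
                lbl = groups.label(b)
                strength = float(strengths[b])
                if mode == "friend":
                    edge = DiagramEdge(parent.label, lbl, stage_name, strength)
                else:
                    edge = DiagramEdge(lbl, parent.label, stage_name, strength)
                graph.edges.append(edge)
                if lbl not in placed:
                    node = DiagramNode(label=lbl, position=b, level=stage,
                                       parent=parent.label)
                    placed[lbl] = node
                    graph.nodes.append(node)
                    next_frontier.append(node)
        frontier = next_frontier
    return graph


def assign_subgroup_colors(
    graph: DiagramGraph, g_nd: np.ndarray, groups: ProteinGroupTable
) -> DiagramGraph:
    """Color nodes by subgroup and leading-protein affinity.

    TGF-beta and X nodes are red.  An up-protein Uj is olive when it is a
    strictly stronger follower of U1 than of U2 on ``g_nd`` (the
    Grr + Gqr(nd) matrix), i.e. g_nd(U1, Uj) > g_nd(U2, Uj), and green
    otherwise; down-proteins are cyan/blue by the same comparison against
    D1/D2.  The leading proteins keep their own colors by definition.
    """
    try:
        u1 = groups.position_of_label("U1")
        u2 = groups.position_of_label("U2")
        d1 = groups.position_of_label("D1")
        d2 = groups.position_of_label("D2")
    except ValueError as exc:
        raise ValueError(f"color rule needs U1, U2, D1, D2 rows: {exc}") from exc
    fixed = {"U1": "olive", "U2": "green", "D1": "cyan", "D2": "blue"}
    for node in graph.nodes:
        sub = groups.frame.iloc[node.position]["subgroup"]
        if sub in RED_SUBGROUPS:
            node.color = "red"
        elif node.label in fixed:
            node.color = fixed[node.label]
        elif sub == "u":
            node.color = "olive" if g_nd[u1, node.position] > g_nd[u2, node.position] else "green"
        else:
            node.color = "cyan" if g_nd[d1, node.position] > g_nd[d2, node.position] else "blue"
    return graph


def _to_networkx(graph: DiagramGraph) -> nx.MultiDiGraph:
    g = nx.MultiDiGraph(mode=graph.mode, source_matrix=graph.source_matrix)
    for n in graph.nodes:
        g.add_node(n.label, level=n.level, parent=n.parent or "",
                   color=n.color or "", position=n.position)
    for e in graph.edges:
        g.add_edge(e.src, e.dst, stage=e.stage, strength=e.strength)
    return g


def export_diagram(graph: DiagramGraph, path, format: str = "dot") -> None:
    """Write the diagram as DOT or GraphML with level/color/stage attributes.

    Primary-stage edges carry bold style, secondary thin red — attributes
    only; layout is the renderer's job.
    """
    if format == "graphml":
        nx.write_graphml(_to_networkx(graph), path)
        return
    if format != "dot":
        raise ValueError(f"unsupported format {format!r} (use 'dot' or 'graphml')")
    lines = [f'digraph "{graph.mode}_{graph.source_matrix}" {{']
    for n in graph.nodes:
        color = n.color or "black"
        lines.append(
            f'  "{n.label}" [level={n.level} color="{color}" '
            f'fillcolor="{color}" style=filled];'
        )
    for e in graph.edges:
        style = 'style=bold color="black"' if e.stage == "primary" \
            else 'style=solid color="red" penwidth=0.5'
        lines.append(
            f'  "{e.src}" -> "{e.dst}" [{style} stage="{e.stage}" '
            f'strength="{e.strength:.6g}"];'
        )
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
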