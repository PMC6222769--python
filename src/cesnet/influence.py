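"""Node-influence quantities and central node/edge selection.

The influence between two nodes is their degree product divided by the
squared Jaccard distance of their neighborhoods,

    IB(v1, v2) = D(v1) * D(v2) / (1 - SIM(v1, v2))**2,

and a node's total influence ALL(v) sums IB over its neighbors.  Central
nodes are picked greedily in descending ALL order under two constraints: a
candidate must not be adjacent to an already selected central node, and it
must be a local maximum of the *current* ALL values.  After each selection
the neighbors' ALL values are recomputed and scaled by the community
magnetic interference factor ``gf`` — damping (gf < 1) lets additional
centers emerge near an existing one, boosting (gf > 1) suppresses them.

Every edge incident to the i-th central node forms the i-th central-edge
category; all remaining edges are non-central and are attached to a category
by the edge-clustering stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .graph_io import EmptyGraphError

__all__ = [
    "EPS_DISTANCE",
    "auto_gf",
    "auto_prop",
    "jaccard_sim",
    "pair_influence",
    "all_influence",
    "NodeInfluenceTable",
    "select_central_nodes",
    "CentralEdgeCategories",
    "select_central_edges",
    "canonical_edge",
]

#: Floor on the Jaccard distance 1 - SIM when two nodes have identical
#: neighborhoods (SIM = 1 would make the influence denominator vanish).
EPS_DISTANCE = 1e-6


def auto_gf(g: nx.Graph) -> float:
    """Benchmark default for the interference factor: 4.2 * n / m."""
    m = g.number_of_edges()
    if m == 0:
        raise EmptyGraphError("graph has no edges")
    return 4.2 * g.number_of_nodes() / m


def auto_prop(g: nx.Graph) -> float:
    """Benchmark default for the pruning threshold: n / m (capped at 1)."""
    m = g.number_of_edges()
    if m == 0:
        raise EmptyGraphError("graph has no edges")
    return min(1.0, g.number_of_nodes() / m)


def canonical_edge(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def jaccard_sim(g: nx.Graph, v1: str, v2: str) -> float:
    """Jaccard similarity of the two open neighborhoods; 0 when both empty."""
    n1, n2 = set(g[v1]), set(g[v2])
    union = n1 | n2
    if not union:
        return 0.0
    return len(n1 & n2) / len(union)


def pair_influence(g: nx.Graph, v1: str, v2: str, eps_distance: float = EPS_DISTANCE) -> float:
    """Influence IB(v1, v2) between two distinct nodes.

    When the neighborhoods coincide (SIM = 1) the Jaccard distance is floored
    at ``eps_distance`` instead of dividing by zero; duplicate-neighborhood
    pairs do occur in real interaction networks.
    """
    if v1 == v2:
        raise ValueError("pair influence is undefined for a node with itself")
    dist = max(1.0 - jaccard_sim(g, v1, v2), eps_distance)
    return g.degree(v1) * g.degree(v2) / (dist * dist)


def all_influence(g: nx.Graph, v: str, eps_distance: float = EPS_DISTANCE) -> float:
    """Total influence ALL(v) = sum of IB(v, u) over neighbors u; 0 if isolated."""
    return sum(pair_influence(g, v, u, eps_distance) for u in g[v])


@dataclass
class NodeInfluenceTable:
    """State of the central-node selection: current ALL values, the ordered
    central-node list, and the blocked set (neighbors of selected centers)."""

    all_value: dict[str, float]
    central_nodes: list[str] = field(default_factory=list)
    blocked: set[str] = field(default_factory=set)


def select_central_nodes(
    g: nx.Graph,
    gf: float | None = None,
    eps_distance: float = EPS_DISTANCE,
) -> NodeInfluenceTable:
    """Greedy central-node selection with community magnetic interference.

    Nodes are visited once, in descending initial-ALL order (ties broken by
    lexicographic label).  A node is selected iff it is not blocked (not
    adjacent to a previously selected center) and no neighbor has a strictly
    larger ALL value in the current table.  On selection its ALL is zeroed,
    its neighbors are blocked, and each neighbor's ALL is recomputed from the
    graph and scaled by ``gf``.

    Isolated nodes never become central.  Raises on empty graphs; any graph
    with at least one edge yields at least one central node (the global ALL
    maximum always qualifies).
    """
    if g.number_of_nodes() == 0:
        raise EmptyGraphError("cannot select central nodes of an empty graph")
    if g.number_of_edges() == 0:
        raise EmptyGraphError("graph has no edges; no central nodes exist")
    if gf is None:
        gf = auto_gf(g)
    if gf <= 0:
        raise ValueError(f"gf must be positive, got {gf}")

    table = NodeInfluenceTable(
        all_value={v: all_influence(g, v, eps_distance) for v in g.nodes}
    )
    order = sorted(g.nodes, key=lambda v: (-table.all_value[v], v))
    av = table.all_value
    for v in order:
        if g.degree(v) == 0 or v in table.blocked:
            continue
        if any(av[u] > av[v] for u in g[v]):
            continue
        table.central_nodes.append(v)
        av[v] = 0.0
        table.blocked.update(g[v])
        for vv in g[v]:
            av[vv] = gf * all_influence(g, vv, eps_distance)
    return table


@dataclass(frozen=True)
class CentralEdgeCategories:
    """Central-edge categories CE_i: for each central node, the set of its
    incident edges.  Central nodes are pairwise non-adjacent, so the
    categories are disjoint; ``noncentral`` is the complement in E."""

    categories: dict[int, frozenset[tuple[str, str]]]
    central_node_of: dict[int, str]
    noncentral: frozenset[tuple[str, str]]

    def category_of_central_edge(self, edge: tuple[str, str]) -> int | None:
        e = canonical_edge(*edge)
        for i, edges in self.categories.items():
            if e in edges:
                return i
        return None


def select_central_edges(g: nx.Graph, table: NodeInfluenceTable) -> CentralEdgeCategories:
    """Partition E into per-central-node categories plus the non-central rest."""
    if not table.central_nodes:
        raise ValueError("no central nodes selected")
    categories: dict[int, frozenset[tuple[str, str]]] = {}
    central_node_of: dict[int, str] = {}
    taken: set[tuple[str, str]] = set()
    for i, cn in enumerate(table.central_nodes, 1):
        edges = frozenset(canonical_edge(cn, u) for u in g[cn])
        categories[i] = edges
        central_node_of[i] = cn
        taken |= edges
    noncentral = frozenset(
        canonical_edge(*e) for e in g.edges if canonical_edge(*e) not in taken
    )
    return CentralEdgeCategories(categories, central_node_of, noncentral)
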