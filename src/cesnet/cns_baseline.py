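"""The central-node-selection (CNS) baseline.

CNS picks every node whose total influence ALL(v) is a local maximum over
its neighborhood (no interference revision, no adjacency blocking beyond
the local-maximum rule itself), seeds one community per central node, and
grows each community by repeatedly absorbing frontier nodes whose
``attract`` value — the share of their total influence pointing into the
community — exceeds a threshold (0.4 by default).  Nodes can be absorbed
by several communities, which is the only source of overlap; nodes never
reached by any expansion stay uncovered.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import networkx as nx

from .graph_io import Cover, EmptyGraphError
from .influence import EPS_DISTANCE, all_influence, pair_influence

__all__ = ["CnsConfig", "cns_central_nodes", "attract", "cns_detect"]


@dataclass(frozen=True)
class CnsConfig:
    epsilon: float = 0.4

    def __post_init__(self) -> None:
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError(f"epsilon must be in (0, 1), got {self.epsilon}")


def cns_central_nodes(g: nx.Graph, eps_distance: float = EPS_DISTANCE) -> list[str]:
    """All local maxima of ALL(v); adjacent exact ties are broken in favor of
    the lexicographically smaller label, isolated nodes are never central."""
    if g.number_of_nodes() == 0:
        raise EmptyGraphError("cannot select central nodes of an empty graph")
    av = {v: all_influence(g, v, eps_distance) for v in g.nodes}
    central = []
    for v in sorted(g.nodes):
        if g.degree(v) == 0:
            continue
        dominated = any(
            av[u] > av[v] or (av[u] == av[v] and u < v) for u in g[v]
        )
        if not dominated:
            central.append(v)
    return central


def attract(
    g: nx.Graph,
    community: Iterable[str],
    u: str,
    all_value: float | None = None,
    eps_distance: float = EPS_DISTANCE,
) -> float:
    """Share of u's total influence directed into the community:
    sum of IB(u, v) over community members adjacent to u, over ALL(u).
    Returns 0 for a node with no influence (isolated)."""
    if all_value is None:
        all_value = all_influence(g, u, eps_distance)
    if all_value <= 0.0:
        return 0.0
    members = set(community)
    num = sum(
        pair_influence(g, u, v, eps_distance) for v in g[u] if v in members
    )
    return num / all_value


def cns_detect(
    g: nx.Graph,
    cfg: CnsConfig | None = None,
    eps_distance: float = EPS_DISTANCE,
) -> Cover:
    """Run the full CNS baseline and return the (possibly partial) cover.

    Expansion is synchronous: each round evaluates every community's
    frontier against the round-start node sets, so the result does not
    depend on processing order.  Membership only grows, so termination is
    bounded by n rounds per community.
    """
    cfg = cfg or CnsConfig()
    central = cns_central_nodes(g, eps_distance)
    if not central:
        raise EmptyGraphError("graph has no edges; no communities exist")
    av = {v: all_influence(g, v, eps_distance) for v in g.nodes}
    comms: dict[int, set[str]] = {i: {cn} for i, cn in enumerate(central, 1)}
    changed = True
    while changed:
        changed = False
        snapshot = {i: frozenset(s) for i, s in comms.items()}
        for i, members in snapshot.items():
            frontier = {u for v in members for u in g[v]} - members
            for u in sorted(frontier):
                if attract(g, members, u, av[u], eps_distance) > cfg.epsilon:
                    comms[i].add(u)
                    changed = True
    return Cover.from_communities(comms)
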