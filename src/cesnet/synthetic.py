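"""Synthetic benchmark graphs with planted overlapping communities.

The planted model is a chain of ``n_communities`` dense blocks of ``size``
nodes in which every pair of consecutive blocks shares ``n_overlap``
boundary nodes.  Within-block node pairs receive an edge with probability
``p_in``, all remaining pairs with probability ``p_out`` (p_out < p_in).
The generator returns the graph together with its ground-truth cover
(boundary nodes carry two memberships), is fully deterministic under the
spec's seed, and resamples a block a bounded number of times if a draw
leaves it internally disconnected.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graph_io import Cover

__all__ = ["PlantedSpec", "planted_graph", "demo_fixture", "InfeasibleSpecError"]


class InfeasibleSpecError(ValueError):
    """Raised when a planted spec cannot produce connected communities."""


@dataclass(frozen=True)
class PlantedSpec:
    n_communities: int = 3
    size: int = 20
    n_overlap: int = 2
    p_in: float = 0.9
    p_out: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_communities < 2:
            raise InfeasibleSpecError("need at least 2 communities")
        if not 0.0 <= self.p_out < self.p_in <= 1.0:
            raise InfeasibleSpecError("require 0 <= p_out < p_in <= 1")
        if not 0 <= self.n_overlap < self.size:
            raise InfeasibleSpecError("require 0 <= n_overlap < size")
        # a block must have a chance of being connected at all
        if self.size > 1 and self.p_in == 0.0:
            raise InfeasibleSpecError("p_in = 0 cannot connect a community")


_MAX_RETRIES = 50


def planted_graph(spec: PlantedSpec) -> tuple[nx.Graph, Cover]:
    """Sample a planted-overlap graph and its ground-truth cover."""
    rng = np.random.default_rng(spec.seed)

    blocks: list[list[str]] = []
    next_id = 0
    carried: list[str] = []
    for i in range(spec.n_communities):
        fresh = [
            f"n{j:04d}" for j in range(next_id, next_id + spec.size - len(carried))
        ]
        next_id += len(fresh)
        members = carried + fresh
        blocks.append(members)
        carried = (
            members[-spec.n_overlap :]
            if spec.n_overlap and i < spec.n_communities - 1
            else []
        )

    nodes = sorted({v for block in blocks for v in block})
    idx = {v: i for i, v in enumerate(nodes)}
    member = np.zeros((len(nodes), len(blocks)), dtype=bool)
    for j, block in enumerate(blocks):
        for v in block:
            member[idx[v], j] = True
    shared = member @ member.T  # pair shares >=1 block -> within-community
    ai, bi = np.triu_indices(len(nodes), k=1)
    prob = np.where(shared[ai, bi], spec.p_in, spec.p_out)

    # one Bernoulli draw per node pair; resample the whole graph while any
    # planted community is internally disconnected
    for _ in range(_MAX_RETRIES):
        keep = rng.random(len(prob)) < prob
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(
            (nodes[a], nodes[b]) for a, b in zip(ai[keep], bi[keep])
        )
        if all(
            len(block) <= 1 or nx.is_connected(g.subgraph(block))
            for block in blocks
        ):
            break
    else:
        raise InfeasibleSpecError(
            f"a community of size {spec.size} stayed internally disconnected "
            f"at p_in={spec.p_in} after {_MAX_RETRIES} draws"
        )

    truth = Cover.from_communities(
        {i: frozenset(b) for i, b in enumerate(blocks, 1)}
    )
    return g, truth


#: Two dense 4-node blocks {1,2,3,4,5} and {4,5,6,7,8} sharing nodes 4 and 5
#: (12 edges).  Node 3 dominates the whole graph's influence and node 6 is
#: dominated by the shared nodes, so plain local-maximum selection finds one
#: center while interference-revised selection at damping gf (< 1) finds two.
_DEMO_EDGES = [
    ("1", "3"), ("1", "4"), ("1", "5"), ("2", "3"), ("3", "4"), ("3", "5"),
    ("4", "6"), ("4", "7"), ("5", "6"), ("5", "8"), ("6", "7"), ("6", "8"),
]

#: gf used when demonstrating the two-center contrast on the demo graph.
DEMO_GF = 0.5


def demo_fixture() -> tuple[nx.Graph, Cover]:
    """The 8-node / 12-edge two-block demonstration graph and its cover.

    This is a synthetic reconstruction of the classic motivating example
    (the original drawing's adjacency is not published): two overlapping
    dense blocks whose shared nodes belong to both communities.
    """
    g = nx.Graph(_DEMO_EDGES)
    truth = Cover.from_communities(
        {1: {"1", "2", "3", "4", "5"}, 2: {"4", "5", "6", "7", "8"}}
    )
    return g, truth
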