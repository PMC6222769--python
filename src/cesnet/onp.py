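"""Overlapping-node pruning (ONP).

Edge clustering hands every node the union of its incident edges'
categories, which overstates the genuine overlap; pruning removes weak
memberships with two strategies:

1. a membership supported *only* by central edges of that category is
   dropped (a single tie to a community's center is not evidence of
   membership);
2. a membership whose connection share con(v, C_j) / sum_k con(v, C_k)
   falls below the threshold ``prop`` is dropped.

``con`` can be counted two ways, and the choice matters at the margins:
``"nodes"`` counts all edges from v into the community's current node set
(the default), ``"edges"`` counts v's incident edges labeled with the
category.  Strategy 1 runs first; all strategy-2 proportions are computed
on the post-strategy-1 cover and then applied in one batch (no cascade).
A node never loses its last membership and a removal that would empty a
community is skipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .edge_clustering import EdgeAssignment
from .graph_io import Cover
from .influence import CentralEdgeCategories, canonical_edge

__all__ = ["PruneConfig", "prune_cover"]


@dataclass(frozen=True)
class PruneConfig:
    """Pruning parameters.

    prop: threshold in [0, 1] for the proportional rule (strategy 2).
    con_mode: "nodes" counts edges into the community node set, "edges"
        counts incident edges carrying the category label (requires the
        edge assignment).
    """

    prop: float
    con_mode: str = "nodes"

    def __post_init__(self) -> None:
        if not 0.0 <= self.prop <= 1.0:
            raise ValueError(f"prop must be in [0, 1], got {self.prop}")
        if self.con_mode not in ("nodes", "edges"):
            raise ValueError(f"con_mode must be 'nodes' or 'edges', got {self.con_mode!r}")


def _overlapping(membership: dict[str, set[int]]) -> list[str]:
    # descending overlap degree, then lexicographic: deterministic order
    return sorted(
        (v for v, ids in membership.items() if len(ids) > 1),
        key=lambda v: (-len(membership[v]), v),
    )


def prune_cover(
    g: nx.Graph,
    cover: Cover,
    cec: CentralEdgeCategories,
    cfg: PruneConfig,
    ea: EdgeAssignment | None = None,
) -> Cover:
    """Return a pruned copy of ``cover``; community ids are preserved (they
    still index the central-edge categories), empty communities cannot arise.
    """
    if cfg.con_mode == "edges" and ea is None:
        raise ValueError("con_mode='edges' requires the edge assignment")

    membership = {v: set(ids) for v, ids in cover.membership.items()}
    communities = {c: set(nodes) for c, nodes in cover.communities.items()}
    central_of = cec.central_node_of

    def con(v: str, j: int) -> int:
        if cfg.con_mode == "nodes":
            return sum(1 for w in g[v] if w in communities[j])
        return sum(
            1 for w in g[v] if ea.category_of.get(canonical_edge(v, w)) == j
        )

    def remove(v: str, j: int) -> None:
        if len(membership[v]) <= 1 or len(communities[j]) <= 1:
            return
        membership[v].discard(j)
        communities[j].discard(v)

    # strategy 1: membership held only through central edges of the category
    for v in _overlapping(membership):
        for j in sorted(membership[v]):
            if len(membership[v]) <= 1:
                break
            if cfg.con_mode == "nodes":
                ties = [canonical_edge(v, w) for w in g[v] if w in communities[j]]
            else:
                ties = [
                    canonical_edge(v, w)
                    for w in g[v]
                    if ea.category_of.get(canonical_edge(v, w)) == j
                ]
            if ties and all(central_of[j] in e for e in ties):
                remove(v, j)

    # strategy 2: proportions frozen on the post-strategy-1 cover
    frozen = {
        v: {j: con(v, j) for j in membership[v]} for v in _overlapping(membership)
    }
    for v, cons in frozen.items():
        total = sum(cons.values())
        if total == 0:
            continue
        # strongest membership (ties -> lower community id) is never flagged
        # away when everything falls below the threshold
        strongest = min(cons, key=lambda j: (-cons[j], j))
        flagged = [j for j in sorted(cons) if cons[j] / total < cfg.prop]
        for j in flagged:
            if len(membership[v]) <= 1:
                break
            if j == strongest and len(flagged) == len(cons):
                continue
            remove(v, j)

    return Cover(
        membership={v: frozenset(s) for v, s in membership.items()},
        communities={c: frozenset(s) for c, s in communities.items() if s},
    )
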