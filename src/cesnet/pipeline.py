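"""The composed CES detection pipeline.

Stages: central-node selection with interference revision -> central-edge
categories -> DNC edge clustering -> edge-to-node cover conversion ->
overlapping-node pruning -> id normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .edge_clustering import (
    EdgeAssignment,
    assign_noncentral_edges,
    edges_to_cover,
)
from .graph_io import Cover
from .influence import (
    EPS_DISTANCE,
    CentralEdgeCategories,
    NodeInfluenceTable,
    auto_gf,
    auto_prop,
    select_central_edges,
    select_central_nodes,
)
from .onp import PruneConfig, prune_cover

__all__ = ["CesResult", "ces_detect"]


@dataclass(frozen=True)
class CesResult:
    """Cover plus the intermediate state of each stage."""

    cover: Cover
    raw_cover: Cover
    table: NodeInfluenceTable
    categories: CentralEdgeCategories
    assignment: EdgeAssignment
    gf: float
    prop: float


def ces_detect(
    g: nx.Graph,
    gf: float | str = "auto",
    prop: float | str = "auto",
    *,
    dnc_rule: str = "max",
    con_mode: str = "nodes",
    prune: bool = True,
    eps_distance: float = EPS_DISTANCE,
) -> CesResult:
    """Detect overlapping communities by central edge selection.

    ``gf="auto"`` resolves to 4.2 * n / m, ``prop="auto"`` to n / m.  The
    returned cover has contiguous community ids; the raw (pre-normalization,
    pre-pruning) cover and all intermediates are kept for inspection.
    """
    gf_val = auto_gf(g) if gf == "auto" else float(gf)
    prop_val = auto_prop(g) if prop == "auto" else float(prop)

    table = select_central_nodes(g, gf_val, eps_distance)
    cec = select_central_edges(g, table)
    ea = assign_noncentral_edges(g, cec, rule=dnc_rule)
    raw = edges_to_cover(g, ea)
    cover = raw
    if prune:
        cover = prune_cover(g, raw, cec, PruneConfig(prop_val, con_mode), ea)
    cover = Cover.from_membership(cover.membership)
    return CesResult(
        cover=cover,
        raw_cover=raw,
        table=table,
        categories=cec,
        assignment=ea,
        gf=gf_val,
        prop=prop_val,
    )
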