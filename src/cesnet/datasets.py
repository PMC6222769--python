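"""Bundled benchmark data.

Only Zachary's karate club ships with the package (via networkx).  The
dolphin social network and the American college football network are
public but not redistributed here; load them from local files with
:func:`cesnet.graph_io.read_edge_list` / :func:`read_cover`.
"""

from __future__ import annotations

import networkx as nx

from .graph_io import Cover

__all__ = ["karate_graph", "karate_reference"]

#: Mr. Hi's faction in Zachary's (1977) karate-club study, 1-based actor ids.
#: This is the standard two-community benchmark division: actor 9 sided with
#: the officers' faction even though he joined Mr. Hi's club after the split,
#: so he is *not* in this set (networkx's ``club`` node attribute records the
#: club joined, which differs for this one actor).
_MR_HI_FACTION = frozenset({
    "01", "02", "03", "04", "05", "06", "07", "08",
    "11", "12", "13", "14", "17", "18", "20", "22",
})


def karate_graph() -> nx.Graph:
    """Zachary's karate club (34 nodes, 78 edges) with string labels 01..34."""
    g = nx.karate_club_graph()
    return nx.relabel_nodes(g, {i: f"{i + 1:02d}" for i in g.nodes})


def karate_reference() -> Cover:
    """The canonical two-faction reference division of the karate club."""
    g = karate_graph()
    officers = frozenset(g.nodes) - _MR_HI_FACTION
    return Cover.from_communities({1: _MR_HI_FACTION, 2: officers})
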