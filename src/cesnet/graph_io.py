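"""Edge-list and overlapping-cover I/O, plus the graph normalization all
algorithms in this package assume.

Graphs are plain :class:`networkx.Graph` objects over opaque *string* node
labels: undirected, unweighted, no self-loops, no parallel edges.  Covers
(overlapping node partitions) are :class:`Cover` objects mapping each node to
a non-empty set of integer community ids (contiguous, starting at 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "Cover",
    "EmptyGraphError",
    "CoverFormatError",
    "read_edge_list",
    "write_edge_list",
    "read_graphml",
    "normalize_graph",
    "filter_components",
    "read_cover",
    "write_cover",
]


class EmptyGraphError(ValueError):
    """Raised when an operation requires at least one edge/node."""


class CoverFormatError(ValueError):
    """Raised for malformed cover files or inconsistent cover structures."""


@dataclass(frozen=True)
class Cover:
    """An overlapping node partition.

    ``membership`` maps each covered node to its non-empty set of community
    ids; ``communities`` is the inverse mapping.  Community ids are contiguous
    integers starting at 1.  Nodes of a graph that are absent from
    ``membership`` are *uncovered* (this is what drives a coverage rate below
    100%).
    """

    membership: Mapping[str, frozenset[int]]
    communities: Mapping[int, frozenset[str]]

    @staticmethod
    def from_membership(membership: Mapping[str, Iterable[int]]) -> "Cover":
        """Build a normalized Cover from a node -> community-ids mapping.

        Ids are remapped to contiguous integers (1..k) by first appearance in
        sorted node order; empty membership sets are rejected.
        """
        remap: dict[object, int] = {}
        memb: dict[str, frozenset[int]] = {}
        for node in sorted(membership):
            ids = list(membership[node])
            if not ids:
                raise CoverFormatError(f"node {node!r} has an empty community list")
            for c in ids:
                if c not in remap:
                    remap[c] = len(remap) + 1
            memb[node] = frozenset(remap[c] for c in ids)
        comms: dict[int, set[str]] = {}
        for node, ids in memb.items():
            for c in ids:
                comms.setdefault(c, set()).add(node)
        return Cover(
            membership=memb,
            communities={c: frozenset(s) for c, s in comms.items()},
        )

    @staticmethod
    def from_communities(communities: Mapping[int, Iterable[str]]) -> "Cover":
        memb: dict[str, set[int]] = {}
        for c in sorted(communities):
            nodes = set(communities[c])
            if not nodes:
                continue
            for v in nodes:
                memb.setdefault(v, set()).add(c)
        if not memb:
            raise CoverFormatError("cover has no non-empty community")
        return Cover.from_membership(memb)

    @property
    def n_communities(self) -> int:
        return len(self.communities)

    def overlap_count(self, node: str) -> int:
        """Number of communities the node belongs to (O_v); 0 if uncovered."""
        return len(self.membership.get(node, ()))

    def overlapping_nodes(self) -> list[str]:
        return sorted(v for v, ids in self.membership.items() if len(ids) > 1)

    def covered_nodes(self) -> frozenset[str]:
        return frozenset(self.membership)

    def validate(self) -> None:
        ids = sorted(self.communities)
        if ids != list(range(1, len(ids) + 1)):
            raise CoverFormatError(f"community ids not contiguous from 1: {ids}")
        inv: dict[str, set[int]] = {}
        for c, nodes in self.communities.items():
            if not nodes:
                raise CoverFormatError(f"community {c} is empty")
            for v in nodes:
                inv.setdefault(v, set()).add(c)
        if {v: frozenset(s) for v, s in inv.items()} != dict(self.membership):
            raise CoverFormatError("membership and communities are inconsistent")


def normalize_graph(g: nx.Graph) -> nx.Graph:
    """Return an undirected simple copy: string labels, no self-loops, no
    parallel edges, all data stripped."""
    out = nx.Graph()
    out.add_nodes_from(str(v) for v in g.nodes)
    n_loops = 0
    for a, b in g.edges:
        a, b = str(a), str(b)
        if a == b:
            n_loops += 1
            continue
        out.add_edge(a, b)
    if n_loops:
        logger.warning("dropped %d self-loop(s) during normalization", n_loops)
    return out


def read_edge_list(path: str | Path, comment_prefix: str = "#") -> nx.Graph:
    """Read a plain-text edge list: one edge per line, two whitespace-separated
    node labels (extra tokens, e.g. a weight column, are ignored with a
    warning).  Duplicate and reversed-duplicate lines collapse to one edge;
    self-loop lines are dropped.
    """
    g = nx.Graph()
    n_extra = n_loops = 0
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(comment_prefix):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise CoverFormatError(
                    f"{path}:{lineno}: expected at least two tokens, got {line!r}"
                )
            if len(tokens) > 2:
                n_extra += 1
            a, b = tokens[0], tokens[1]
            if a == b:
                n_loops += 1
                g.add_node(a)
                continue
            g.add_edge(a, b)
    if n_extra:
        logger.warning(
            "%s: ignored extra columns on %d line(s) (weights are not used)",
            path, n_extra,
        )
    if n_loops:
        logger.warning("%s: dropped %d self-loop line(s)", path, n_loops)
    if g.number_of_edges() == 0:
        raise EmptyGraphError(f"{path}: no edges after normalization")
    return g


def write_edge_list(g: nx.Graph, path: str | Path) -> None:
    """Write a deterministic edge list (each edge once, endpoints and lines
    sorted lexicographically)."""
    with open(path, "wt", encoding="utf-8") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in g.edges):
            fh.write(f"{a}\t{b}\n")


def read_graphml(path: str | Path) -> nx.Graph:
    """Convenience GraphML reader; the edge list is the primary contract."""
    return normalize_graph(nx.read_graphml(path))


def filter_components(g: nx.Graph, min_size: int = 1) -> nx.Graph:
    """Drop connected components with fewer than ``min_size`` nodes.

    Disconnected graphs are accepted everywhere; this filter only exists for
    protein-interaction-style inputs where tiny fragments are conventionally
    discarded before module detection.
    """
    if min_size <= 1:
        return g
    keep = [c for c in nx.connected_components(g) if len(c) >= min_size]
    return g.subgraph(set().union(*keep) if keep else set()).copy()


def read_cover(path: str | Path) -> Cover:
    """Read a cover file: ``node<TAB>c1[,c2,...]`` per line.  Community labels
    are remapped to contiguous integers by first appearance (in sorted node
    order), so arbitrary labels round-trip into canonical form."""
    raw: dict[str, list[str]] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            try:
                node, ids = line.split("\t", 1)
            except ValueError as exc:
                raise CoverFormatError(f"{path}:{lineno}: expected node<TAB>ids") from exc
            ids = [tok.strip() for tok in ids.split(",") if tok.strip()]
            if not ids:
                raise CoverFormatError(f"{path}:{lineno}: empty community list")
            raw[node] = ids
    if not raw:
        raise CoverFormatError(f"{path}: empty cover file")
    return Cover.from_membership(raw)


def write_cover(cover: Cover, path: str | Path) -> None:
    """Write a cover deterministically: nodes sorted lexicographically, each
    node's community ids ascending."""
    with open(path, "wt", encoding="utf-8") as fh:
        for node in sorted(cover.membership):
            ids = ",".join(str(c) for c in sorted(cover.membership[node]))
            fh.write(f"{node}\t{ids}\n")
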