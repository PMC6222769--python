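"""Cover-quality metrics for overlapping community detection.

* **EQ** — extended modularity: the Newman modularity double sum with each
  node pair down-weighted by the product of the two nodes' membership
  counts O_v O_w.  For a non-overlapping cover (all O_v = 1) it reduces to
  standard modularity.
* **overlapping NMI** — the LFK construction: each community is a binary
  node-membership random variable; the score is one minus the mean of the
  two normalized conditional entropies H(X|Y)_norm and H(Y|X)_norm, where
  H(X_k|Y) takes the best (minimum) admissible conditional entropy over the
  communities of the other cover, normalized by H(X_k).
* **CR** — coverage rate: the percentage of graph nodes holding at least
  one membership.
* **ECN** — the number of (non-empty) communities produced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import networkx as nx

from .graph_io import Cover, EmptyGraphError

__all__ = ["EvalReport", "eq_score", "onmi_score", "cr_score", "evaluate"]


@dataclass(frozen=True)
class EvalReport:
    eq: float
    nmi: float | None
    cr: float
    ecn: int

    def as_dict(self) -> dict:
        return {"eq": self.eq, "nmi": self.nmi, "cr": self.cr, "ecn": self.ecn}


def eq_score(g: nx.Graph, cover: Cover) -> float:
    """Extended modularity of a cover.

    The inner sum runs over ordered node pairs (v, w) within each community,
    v = w included with A_vv = 0, so the all-nodes single community scores
    exactly zero.
    """
    m = g.number_of_edges()
    if m == 0:
        raise EmptyGraphError("EQ is undefined on a graph without edges")
    for v in cover.membership:
        if v not in g:
            raise ValueError(f"cover node {v!r} missing from graph")
    two_m = 2.0 * m
    deg = dict(g.degree)
    ov = {v: len(ids) for v, ids in cover.membership.items()}
    total = 0.0
    for nodes in cover.communities.values():
        members = sorted(nodes)
        for v in members:
            kv = deg[v]
            ov_v = ov[v]
            adj = g[v]
            for w in members:
                a_vw = 1.0 if w in adj else 0.0
                total += (a_vw - kv * deg[w] / two_m) / (ov_v * ov[w])
    return total / two_m


def _h(p: float) -> float:
    return -p * math.log2(p) if p > 0.0 else 0.0


def _norm_conditional(xs: list[frozenset], ys: list[frozenset], n: int) -> float:
    """Mean over communities X_k of H(X_k | Y) / H(X_k)."""
    terms = []
    for xk in xs:
        p1 = len(xk) / n
        h_xk = _h(p1) + _h(1.0 - p1)
        best = h_xk
        for yl in ys:
            p11 = len(xk & yl) / n
            p10 = len(xk - yl) / n
            p01 = len(yl - xk) / n
            p00 = 1.0 - p11 - p10 - p01
            # admissibility guard: reject pairs whose dependence is mostly
            # "anti" (complement-like), falling back to H(X_k)
            if _h(p11) + _h(p00) < _h(p01) + _h(p10):
                continue
            q1 = len(yl) / n
            h_yl = _h(q1) + _h(1.0 - q1)
            h_joint = _h(p11) + _h(p10) + _h(p01) + _h(p00)
            best = min(best, h_joint - h_yl)
        terms.append(best / h_xk if h_xk > 0.0 else 0.0)
    return sum(terms) / len(terms)


def onmi_score(ref: Cover, pred: Cover, universe: Iterable[str]) -> float:
    """Overlapping normalized mutual information between two covers over a
    common node universe; 1 for identical covers, symmetric in its cover
    arguments, invariant under community relabeling.  Nodes absent from a
    cover count as belonging to none of its communities."""
    nodes = set(universe)
    n = len(nodes)
    if n == 0:
        raise ValueError("empty node universe")
    if not ref.communities or not pred.communities:
        raise ValueError("onmi is undefined for an empty cover")
    xs = [frozenset(c) & nodes for c in ref.communities.values()]
    ys = [frozenset(c) & nodes for c in pred.communities.values()]
    return 1.0 - 0.5 * (
        _norm_conditional(xs, ys, n) + _norm_conditional(ys, xs, n)
    )


def cr_score(g: nx.Graph, cover: Cover) -> float:
    """Coverage rate: percentage of graph nodes with at least one membership."""
    n = g.number_of_nodes()
    if n == 0:
        raise EmptyGraphError("CR is undefined on an empty graph")
    covered = sum(1 for v in g.nodes if v in cover.membership)
    return 100.0 * covered / n


def evaluate(g: nx.Graph, cover: Cover, ref: Cover | None = None) -> EvalReport:
    """Score a cover: EQ, CR, ECN and — when a reference is supplied —
    overlapping NMI over the graph's node set."""
    nmi = onmi_score(ref, cover, g.nodes) if ref is not None else None
    return EvalReport(
        eq=eq_score(g, cover),
        nmi=nmi,
        cr=cr_score(g, cover),
        ecn=cover.n_communities,
    )
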