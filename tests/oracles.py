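"""Independent reference implementations used only to cross-check the
package.  Everything here is a direct, unoptimized transliteration of the
defining formulas on plain set arithmetic / dense matrices and must stay
decoupled from the implementation modules it checks."""

from __future__ import annotations

import math

import networkx as nx
import numpy as np


def sim_oracle(g: nx.Graph, a: str, b: str) -> float:
    inter = len(set(g[a]) & set(g[b]))
    union = len(set(g[a]) | set(g[b]))
    return inter / union if union else 0.0


def ib_oracle(g: nx.Graph, a: str, b: str, eps: float = 1e-6) -> float:
    d = 1.0 - sim_oracle(g, a, b)
    if d < eps:
        d = eps
    return g.degree(a) * g.degree(b) / d**2


def all_oracle(g: nx.Graph, v: str) -> float:
    return sum(ib_oracle(g, v, u) for u in g[v])


def central_nodes_oracle(g: nx.Graph, gf: float) -> list[str]:
    """Pseudocode transliteration of the greedy interference-revised
    selection: one pass in descending initial total-influence order,
    skip blocked nodes and non-local-maxima, zero the chosen node, block
    and rescale its neighbors."""
    av = {v: all_oracle(g, v) for v in g.nodes}
    cn: list[str] = []
    n_cn: set[str] = set()
    for v in sorted(g.nodes, key=lambda u: (-av[u], u)):
        if g.degree(v) == 0:
            continue
        if v in n_cn:
            continue
        if not all(av[u] <= av[v] for u in g[v]):
            continue
        cn.append(v)
        av[v] = 0.0
        n_cn |= set(g[v])
        for vv in g[v]:
            av[vv] = gf * all_oracle(g, vv)
    return cn


def elc_oracle(g: nx.Graph, e1, e2) -> float:
    (a, b), (c, d) = e1, e2
    num = den = 0
    for x, y in ((a, c), (a, d), (b, c), (b, d)):
        num += len(set(g[x]) & set(g[y]))
        den += len(set(g[x]) | set(g[y]))
    return num / den if den else 0.0


def dnc_oracle(g: nx.Graph, ek, cat) -> float:
    s = sum(elc_oracle(g, ek, ej) for ej in cat)
    if s == 0.0:
        return math.inf
    return sum(
        elc_oracle(g, ek, ej) * (s - elc_oracle(g, ek, ej)) / s for ej in cat
    )


def eq_oracle(g: nx.Graph, communities: dict[int, set[str]]) -> float:
    """Brute-force double sum over a dense adjacency matrix."""
    nodes = sorted(g.nodes)
    pos = {v: i for i, v in enumerate(nodes)}
    a = nx.to_numpy_array(g, nodelist=nodes)
    deg = a.sum(axis=1)
    two_m = deg.sum()
    ov = np.zeros(len(nodes))
    for members in communities.values():
        for v in members:
            ov[pos[v]] += 1
    total = 0.0
    for members in communities.values():
        idx = [pos[v] for v in members]
        for i in idx:
            for j in idx:
                total += (a[i, j] - deg[i] * deg[j] / two_m) / (ov[i] * ov[j])
    return total / two_m
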