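"""scikit-learn-style estimators wrapping the detection pipelines.

Both detectors follow the sklearn clustering protocol: construct with
hyper-parameters, call :meth:`fit` on a graph, read fitted attributes
(``cover_``, ``membership_``, ``n_communities_``...).  ``get_params`` /
``set_params`` come from :class:`sklearn.base.BaseEstimator`, so the
detectors compose with ``clone`` and sklearn model-selection utilities.
The estimators' X is a :class:`networkx.Graph` (or an iterable of edges),
not a feature matrix.
"""

from __future__ import annotations

import networkx as nx
from sklearn.base import BaseEstimator

from .cns_baseline import CnsConfig, cns_detect
from .graph_io import Cover, normalize_graph
from .influence import EPS_DISTANCE
from .pipeline import ces_detect

__all__ = ["CESCommunityDetector", "CNSCommunityDetector"]


def _as_graph(X) -> nx.Graph:
    if isinstance(X, nx.Graph):
        return normalize_graph(X)
    g = nx.Graph()
    g.add_edges_from((str(a), str(b)) for a, b in X)
    return normalize_graph(g)


class CESCommunityDetector(BaseEstimator):
    """Overlapping community detection by central edge selection.

    Parameters
    ----------
    gf : float or "auto"
        Community-magnetic-interference factor scaling the revised influence
        of a new center's neighbors; "auto" = 4.2 * n / m.  Values below 1
        damp the neighborhood and allow further centers to emerge nearby.
    prop : float or "auto"
        Pruning threshold on a membership's connection share; "auto" = n / m.
    dnc_rule : {"max", "min"}
        Direction of the DNC category choice for non-central edges.
    con_mode : {"nodes", "edges"}
        How pruning counts a node's connections into a community.
    prune : bool
        Apply overlapping-node pruning (default) or keep the raw cover.

    Attributes
    ----------
    cover_ : Cover
        The detected overlapping cover (contiguous community ids).
    membership_ : dict
        node -> frozenset of community ids.
    central_nodes_ : list of str
        Selected central nodes, in selection order.
    n_communities_ : int
    gf_, prop_ : float
        The resolved parameter values actually used.
    """

    def __init__(
        self,
        gf: float | str = "auto",
        prop: float | str = "auto",
        dnc_rule: str = "max",
        con_mode: str = "nodes",
        prune: bool = True,
        eps_distance: float = EPS_DISTANCE,
    ):
        self.gf = gf
        self.prop = prop
        self.dnc_rule = dnc_rule
        self.con_mode = con_mode
        self.prune = prune
        self.eps_distance = eps_distance

    def fit(self, X, y=None):
        g = _as_graph(X)
        res = ces_detect(
            g,
            gf=self.gf,
            prop=self.prop,
            dnc_rule=self.dnc_rule,
            con_mode=self.con_mode,
            prune=self.prune,
            eps_distance=self.eps_distance,
        )
        self.graph_ = g
        self.result_ = res
        self.cover_ = res.cover
        self.membership_ = dict(res.cover.membership)
        self.central_nodes_ = list(res.table.central_nodes)
        self.n_communities_ = res.cover.n_communities
        self.gf_ = res.gf
        self.prop_ = res.prop
        return self

    def fit_predict(self, X, y=None) -> Cover:
        return self.fit(X).cover_


class CNSCommunityDetector(BaseEstimator):
    """The central-node-selection baseline (local-maximum seeds plus
    attract-threshold expansion); may leave nodes uncovered."""

    def __init__(self, epsilon: float = 0.4, eps_distance: float = EPS_DISTANCE):
        self.epsilon = epsilon
        self.eps_distance = eps_distance

    def fit(self, X, y=None):
        g = _as_graph(X)
        cover = cns_detect(g, CnsConfig(self.epsilon), self.eps_distance)
        self.graph_ = g
        self.cover_ = cover
        self.membership_ = dict(cover.membership)
        self.n_communities_ = cover.n_communities
        return self

    def fit_predict(self, X, y=None) -> Cover:
        return self.fit(X).cover_
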