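"""Krackhardt hierarchy and reciprocity diagnostics of transition graphs.

The hierarchy score measures how tree-like a directed graph is: with
``p`` the proportion of tied (ordered-either-way) node pairs whose tie is
reciprocated, the score is ``1 - p``.  A perfect hierarchy (directed
tree) has no reciprocated ties and scores 1; a fully reversible network,
where every tie runs both ways, scores 0.  By default dyads are evaluated
on the transitive closure (reachability), matching the classical
definition on the reachability relation; a ``direct`` mode evaluates raw
edges instead.  Self-loops are ignored — hierarchy concerns between-state
order.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx

from .inference import TransitionGraph

__all__ = ["HierarchyReport", "DyadCensus", "krackhardt_hierarchy", "reciprocity_summary"]


@dataclass
class HierarchyReport:
    score: float | None  # None when no dyad is tied (undefined)
    p_reciprocated: float | None
    mode: str
    tied_dyads: int
    reciprocated_dyads: int
    n_nodes: int


@dataclass
class DyadCensus:
    mutual: int
    asymmetric: int
    null: int

    @property
    def total(self) -> int:
        return self.mutual + self.asymmetric + self.null


def _as_digraph(graph: TransitionGraph | nx.DiGraph) -> nx.DiGraph:
    g = graph.graph if isinstance(graph, TransitionGraph) else graph
    g = nx.DiGraph(g)
    g.remove_edges_from(nx.selfloop_edges(g))
    return g


def krackhardt_hierarchy(
    graph: TransitionGraph | nx.DiGraph, mode: str = "reachability"
) -> HierarchyReport:
    """Krackhardt hierarchy score ``1 - p`` of a directed graph.

    Parameters
    ----------
    mode:
        ``"reachability"`` (default) evaluates dyads on the transitive
        closure — a dyad (i, j) is tied if i reaches j or j reaches i,
        reciprocated if both.  ``"direct"`` uses the edges as given.

    Returns a report with ``score=None`` when the graph has no tied dyads
    (the score is undefined on an empty relation).
    """
    if mode not in ("reachability", "direct"):
        raise ValueError("mode must be 'reachability' or 'direct'")
    g = _as_digraph(graph)
    if g.number_of_nodes() < 2:
        raise ValueError("need at least 2 nodes")
    rel = nx.transitive_closure(g, reflexive=False) if mode == "reachability" else g
    tied = reciprocated = 0
    for u, v in combinations(g.nodes, 2):
        fwd = rel.has_edge(u, v)
        bwd = rel.has_edge(v, u)
        if fwd or bwd:
            tied += 1
            if fwd and bwd:
                reciprocated += 1
    if tied == 0:
        return HierarchyReport(None, None, mode, 0, 0, g.number_of_nodes())
    p = reciprocated / tied
    return HierarchyReport(1.0 - p, p, mode, tied, reciprocated, g.number_of_nodes())


def reciprocity_summary(graph: TransitionGraph | nx.DiGraph) -> DyadCensus:
    """Dyad census: mutual / asymmetric / null counts over node pairs."""
    g = _as_digraph(graph)
    if g.number_of_nodes() < 2:
        raise ValueError("need at least 2 nodes")
    mutual = asymmetric = null = 0
    for u, v in combinations(g.nodes, 2):
        fwd, bwd = g.has_edge(u, v), g.has_edge(v, u)
        if fwd and bwd:
            mutual += 1
        elif fwd or bwd:
            asymmetric += 1
        else:
            null += 1
    return DyadCensus(mutual=mutual, asymmetric=asymmetric, null=null)
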