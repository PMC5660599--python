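"""Shared-partner weighting of protein-protein interaction edges.

Two interacting proteins that share many interaction partners are more likely
to be subunits of the same complex than two proteins whose only evidence is
the direct edge between them.  Every edge (a, b) is therefore weighted by the
significance of the overlap of the neighbor sets of a and b:

* neighbor sets exclude a and b themselves (their mutual edge is already the
  evidence gating which pairs get scored);
* the universe is all network nodes except a and b (size N);
* p = upper-tail hypergeometric P(X >= n_shared) with population N,
  success states deg(a), draws deg(b);
* score = -log10(p), capped at 300 when p underflows.

Only direct edges are scored; non-interacting pairs carry no interaction
evidence downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import InteractionNetwork

SCORE_CAP = 300.0


@dataclass(frozen=True)
class SharedPartnerScore:
    score: float
    p_value: float
    deg_a: int
    deg_b: int
    n_shared: int
    universe_size: int


def _tail_p(n_shared: int, universe: int, deg_a: int, deg_b: int) -> float:
    if n_shared <= 0:
        return 1.0
    return float(stats.hypergeom.sf(n_shared - 1, universe, deg_a, deg_b))


def _score_from_p(p: float) -> float:
    if p <= 0.0:
        return SCORE_CAP
    return min(-np.log10(p), SCORE_CAP)


def shared_partner_score(
    net: InteractionNetwork, a: str, b: str
) -> SharedPartnerScore:
    """Shared-partner score of a single (unordered) pair of network nodes."""
    if a == b:
        raise ValueError("shared_partner_score requires two distinct genes")
    if a not in net.graph or b not in net.graph:
        raise KeyError(f"gene(s) not in network: {[g for g in (a, b) if g not in net.graph]}")
    na = net.neighbors(a) - {a, b}
    nb = net.neighbors(b) - {a, b}
    universe = net.n_nodes - 2
    shared = len(na & nb)
    p = _tail_p(shared, universe, len(na), len(nb))
    return SharedPartnerScore(
        score=_score_from_p(p),
        p_value=p,
        deg_a=len(na),
        deg_b=len(nb),
        n_shared=shared,
        universe_size=universe,
    )


def weight_network(net: InteractionNetwork) -> InteractionNetwork:
    """Attach a shared-partner score to every edge of the network.

    Returns a new network over the same nodes and edges with per-edge
    ``score`` attributes.
    """
    if net.n_nodes == 0:
        raise ValueError("cannot weight an empty network")
    g = net.graph
    universe = net.n_nodes - 2
    neighbor_sets = {node: set(g.neighbors(node)) for node in g.nodes}
    edges = [tuple(sorted(e)) for e in g.edges]
    deg_a = np.empty(len(edges), dtype=np.int64)
    deg_b = np.empty(len(edges), dtype=np.int64)
    shared = np.empty(len(edges), dtype=np.int64)
    for k, (a, b) in enumerate(edges):
        na = neighbor_sets[a] - {a, b}
        nb = neighbor_sets[b] - {a, b}
        deg_a[k] = len(na)
        deg_b[k] = len(nb)
        shared[k] = len(na & nb)
    p = stats.hypergeom.sf(shared - 1, universe, deg_a, deg_b)
    p = np.where(shared <= 0, 1.0, p)
    out = g.__class__()
    out.add_nodes_from(g.nodes)
    for (a, b), pk in zip(edges, p):
        out.add_edge(a, b, score=_score_from_p(float(pk)), p_value=float(pk))
    return InteractionNetwork.from_graph(out)
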