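"""Network statistics: degree, density, centralization, betweenness.

Conventions (all self-loops ignored):

- degree / neighbor count: number of distinct non-self interaction partners.
- density: mean neighbor count divided by ``n - 1``; 1.0 for a complete
  graph, 0.0 for an edgeless one.
- degree centralization: ``(n / (n - 2)) * (max_degree / (n - 1) - density)``
  — 1.0 for a perfect star, 0.0 when all degrees are equal. A classic
  Freeman normalization (divide the summed degree deviations by
  ``(n - 1)(n - 2)``) is available via ``convention="freeman"``; the two
  coincide on stars and regular graphs.
- betweenness: unweighted shortest-path betweenness (Brandes), normalized by
  ``2 / ((n - 1)(n - 2))`` with ``n`` the whole network's node count even
  when the network is disconnected, so values from one ranking table are
  comparable. ``per_component=True`` renormalizes within each connected
  component instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx

from .errors import UndefinedMetricError
from .interactome import InteractionNetwork


@dataclass(frozen=True)
class TopologySummary:
    """The headline statistics reported per interactome."""

    name: str
    n_nodes: int
    n_interactions: int  # self-loops included
    n_self_loops: int
    avg_neighbors: float
    density: float
    centralization: float


@dataclass(frozen=True)
class CentralityRow:
    protein: str
    degree: int
    betweenness: float
    rank: int


def degree_and_neighbors(network: InteractionNetwork) -> dict[str, tuple[int, int]]:
    """Per-node ``(degree, neighbor_count)``, self-loops excluded.

    In a deduplicated simple graph the two numbers coincide; both are
    returned because they are reported side by side.
    """
    g = network.simple_graph()
    out = {}
    for node in g.nodes:
        nbrs = set(g.neighbors(node)) - {node}
        out[node] = (g.degree(node), len(nbrs))
    return out


def avg_neighbors(network: InteractionNetwork) -> float:
    g = network.simple_graph()
    n = g.number_of_nodes()
    if n == 0:
        return 0.0
    return 2.0 * g.number_of_edges() / n


def density(network: InteractionNetwork) -> float:
    """Average neighbor count normalized by ``n - 1``."""
    n = network.n_nodes
    if n < 2:
        raise UndefinedMetricError(f"density undefined for n={n} (< 2 nodes)")
    return avg_neighbors(network) / (n - 1)


def centralization(
    network: InteractionNetwork, convention: str = "network-analyzer"
) -> float:
    """Degree centralization in [0, 1]; 1.0 for a star, 0.0 for regular graphs."""
    n = network.n_nodes
    if n < 3:
        raise UndefinedMetricError(f"centralization undefined for n={n} (< 3 nodes)")
    g = network.simple_graph()
    degs = [d for _, d in g.degree()]
    dmax = max(degs)
    if convention == "network-analyzer":
        value = (n / (n - 2)) * (dmax / (n - 1) - density(network))
    elif convention == "freeman":
        value = sum(dmax - d for d in degs) / ((n - 1) * (n - 2))
    else:
        raise ValueError(f"unknown centralization convention {convention!r}")
    return min(1.0, max(0.0, value))


def betweenness(
    network: InteractionNetwork, per_component: bool = False
) -> dict[str, float]:
    """Normalized shortest-path betweenness per node.

    Networks with fewer than 3 nodes have no interior vertices; all zeros
    are returned with a warning.
    """
    g = network.simple_graph()
    n = g.number_of_nodes()
    if n < 3:
        warnings.warn(f"betweenness undefined for n={n}; returning zeros")
        return {node: 0.0 for node in g.nodes}
    if per_component:
        out: dict[str, float] = {}
        for comp in nx.connected_components(g):
            sub = g.subgraph(comp)
            if sub.number_of_nodes() < 3:
                out.update({node: 0.0 for node in comp})
            else:
                out.update(nx.betweenness_centrality(sub, normalized=True))
        return out
    return nx.betweenness_centrality(g, normalized=True)


def rank_centrality(
    network: InteractionNetwork, k: int = 25, per_component: bool = False
) -> list[CentralityRow]:
    """Top-``k`` proteins by betweenness, ties broken by identifier."""
    if k < 1:
        raise ValueError("k must be >= 1")
    btw = betweenness(network, per_component=per_component)
    degs = degree_and_neighbors(network)
    if k > len(btw):
        warnings.warn(
            f"requested top {k} of a {len(btw)}-node network; returning all"
        )
        k = len(btw)
    order = sorted(btw.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        CentralityRow(protein=p, degree=degs[p][0], betweenness=b, rank=i)
        for i, (p, b) in enumerate(order[:k], start=1)
    ]


def summarize(network: InteractionNetwork) -> TopologySummary:
    return TopologySummary(
        name=network.name,
        n_nodes=network.n_nodes,
        n_interactions=network.n_interactions,
        n_self_loops=network.n_self_loops,
        avg_neighbors=avg_neighbors(network),
        density=density(network),
        centralization=centralization(network),
    )
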