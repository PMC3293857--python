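"""Shared fixtures and independent brute-force oracles.

The oracle functions here deliberately avoid the library code paths they
check: betweenness is computed by exhaustive simple-path enumeration,
hypergeometric tail probabilities by enumerating all draws, Venn regions by
per-element classification.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import networkx as nx
import numpy as np
import pytest

from nfkbkit.interactome import InteractionNetwork
from nfkbkit.ppi_io import InteractionRecord


# ---------------------------------------------------------------------------
# graph helpers


def net_from_edges(edges, extra_nodes=(), name="test") -> InteractionNetwork:
    records = [InteractionRecord.make(a, b) for a, b in edges]
    return InteractionNetwork.from_records(name, records, extra_nodes=extra_nodes)


def random_network(rng: np.random.Generator, n_max: int = 8) -> InteractionNetwork:
    """A random simple graph on 3..n_max nodes, edge probability 0.1..0.7."""
    n = int(rng.integers(3, n_max + 1))
    p = float(rng.uniform(0.1, 0.7))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    mapping = {i: f"N{i:02d}" for i in g.nodes}
    edges = [(mapping[a], mapping[b]) for a, b in g.edges]
    return net_from_edges(edges, extra_nodes=mapping.values())


# ---------------------------------------------------------------------------
# brute-force oracles


def brute_betweenness(network: InteractionNetwork) -> dict[str, float]:
    """Normalized betweenness by exhaustive enumeration of all simple paths."""
    g = network.simple_graph()
    nodes = sorted(g.nodes)
    n = len(nodes)
    raw = {v: 0.0 for v in nodes}
    adj = {v: set(g.neighbors(v)) - {v} for v in nodes}

    def all_simple_paths(s, t):
        stack = [(s, [s])]
        while stack:
            v, path = stack.pop()
            if v == t:
                yield path
                continue
            for w in adj[v]:
                if w not in path:
                    stack.append((w, path + [w]))

    for s, t in itertools.combinations(nodes, 2):
        paths = list(all_simple_paths(s, t))
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        sps = [p for p in paths if len(p) == shortest]
        for p in sps:
            for v in p[1:-1]:
                raw[v] += 1.0 / len(sps)
    if n < 3:
        return {v: 0.0 for v in nodes}
    scale = 2.0 / ((n - 1) * (n - 2))
    return {v: raw[v] * scale for v in nodes}


def brute_density(network: InteractionNetwork) -> float:
    g = network.simple_graph()
    n = g.number_of_nodes()
    nbr_counts = [len(set(g.neighbors(v)) - {v}) for v in g.nodes]
    return (sum(nbr_counts) / n) / (n - 1)


def brute_centralization(network: InteractionNetwork) -> float:
    g = network.simple_graph()
    n = g.number_of_nodes()
    degs = [len(set(g.neighbors(v)) - {v}) for v in g.nodes]
    val = (n / (n - 2)) * (max(degs) / (n - 1) - brute_density(network))
    return min(1.0, max(0.0, val))


def brute_hypergeom_upper(
    set_size: int, background_size: int, pathway_size: int, hits: int
) -> Fraction:
    """P(X >= hits) by enumerating all C(background, set_size) draws."""
    universe = range(background_size)
    pathway = set(range(pathway_size))
    favorable = 0
    total = 0
    for draw in itertools.combinations(universe, set_size):
        total += 1
        if len(pathway.intersection(draw)) >= hits:
            favorable += 1
    return Fraction(favorable, total)


def brute_direct_interactome(ppi_records, core_members):
    """Induced subgraph on core + first neighbors, computed from scratch."""
    neighbors = {}
    for rec in ppi_records:
        neighbors.setdefault(rec.a, set()).add(rec.b)
        neighbors.setdefault(rec.b, set()).add(rec.a)
    present = {m for m in core_members if m in neighbors}
    node_set = set(present)
    for m in present:
        node_set |= neighbors[m]
    edge_set = {
        rec.pair for rec in ppi_records if rec.a in node_set and rec.b in node_set
    }
    return node_set, edge_set


def brute_venn_regions(a: set, b: set, c: set) -> dict[str, int]:
    counts = {}
    for x in a | b | c:
        patt = f"{int(x in a)}{int(x in b)}{int(x in c)}"
        counts[patt] = counts.get(patt, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(20120305)


@pytest.fixture
def path_network():
    """A path A-B-C-D-E plus an isolated node F."""
    return net_from_edges(
        [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")], extra_nodes=["F"]
    )
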