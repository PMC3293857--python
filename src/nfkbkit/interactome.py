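"""Interactome construction from seed protein sets and a PPI edge table.

An *interactome* here is an undirected network whose nodes are proteins from a
seed set (possibly extended by first neighbors) and whose edges are the
evidence-based physical interactions among them. Two construction rules are
provided:

``direct``
    Seed the network with a small core (e.g. the five NF-kB family members)
    and pull in every protein with experimental evidence of physical
    interaction with at least one core member; edges are, by default, all PPI
    edges among the resulting node set (the full induced subgraph on
    core + first neighbors, which is how Cytoscape-era retrieval plugins
    materialized such queries). ``edges="star"`` restricts to edges touching
    the core.

``induced``
    Take a curated seed list as the node universe and keep only PPI edges
    with both endpoints inside it. Seeds absent from the PPI table are
    excluded from the network but reported.

Self-interactions are kept as edges and counted in the network-level
interaction count; connectivity-based summaries (components, neighbor counts)
ignore them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .errors import EmptyInputError
from .ppi_io import InteractionRecord, ProteinSet

logger = logging.getLogger(__name__)


@dataclass
class InteractionNetwork:
    """A named undirected PPI network with provenance.

    Wraps a :class:`networkx.Graph`; self-loops allowed. ``n_interactions``
    counts distinct unordered pairs *including* self-pairs, matching how
    interaction databases report totals.
    """

    name: str
    graph: nx.Graph
    provenance: dict = field(default_factory=dict)

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_interactions(self) -> int:
        return self.graph.number_of_edges()

    @property
    def n_self_loops(self) -> int:
        return sum(1 for a, b in self.graph.edges if a == b)

    def edge_pairs(self) -> list[tuple[str, str]]:
        """Sorted canonical (a <= b) edge list, self-pairs included."""
        return sorted(tuple(sorted(e)) for e in self.graph.edges)

    def simple_graph(self) -> nx.Graph:
        """Copy of the graph with self-loops removed (for connectivity metrics)."""
        g = self.graph.copy()
        g.remove_edges_from(list(nx.selfloop_edges(g)))
        return g

    @classmethod
    def from_records(
        cls,
        name: str,
        records: Iterable[InteractionRecord],
        extra_nodes: Iterable[str] = (),
        provenance: dict | None = None,
    ) -> "InteractionNetwork":
        g = nx.Graph()
        g.add_nodes_from(extra_nodes)
        for rec in records:
            if g.has_edge(rec.a, rec.b):
                g.edges[rec.a, rec.b]["sources"] = (
                    g.edges[rec.a, rec.b]["sources"] | rec.sources
                )
            else:
                g.add_edge(rec.a, rec.b, sources=frozenset(rec.sources))
        return cls(name=name, graph=g, provenance=dict(provenance or {}))

    def to_records(self) -> list[InteractionRecord]:
        return [
            InteractionRecord(a, b, frozenset(self.graph.edges[a, b].get("sources", ())))
            for a, b in self.edge_pairs()
        ]


@dataclass(frozen=True)
class ComponentSummary:
    """Connected-component structure of a network (self-loops ignored)."""

    main_cluster_size: int
    main_cluster_edges: int
    isolated_count: int
    component_sizes: tuple[int, ...]  # descending

    @property
    def n_nodes(self) -> int:
        return sum(self.component_sizes)


def _ppi_graph(records: Sequence[InteractionRecord]) -> nx.Graph:
    g = nx.Graph()
    for rec in records:
        g.add_edge(rec.a, rec.b)
    return g


def build_direct_interactome(
    ppi: Sequence[InteractionRecord],
    core: ProteinSet,
    name: str = "DI",
    edges: str = "induced",
) -> InteractionNetwork:
    """Core members + all their direct interactors, with PPI edges among them.

    ``edges="induced"`` (default) keeps every PPI edge whose two endpoints
    both fall inside the node set, including neighbor-neighbor edges;
    ``edges="star"`` keeps only edges incident to the core.
    """
    if edges not in ("induced", "star"):
        raise ValueError(f"edges must be 'induced' or 'star', got {edges!r}")
    if not core.members:
        raise EmptyInputError("core set is empty")
    if not ppi:
        raise EmptyInputError("PPI edge table is empty")
    g = _ppi_graph(ppi)
    present = {m for m in core.members if m in g}
    if not present:
        raise EmptyInputError(
            "no core member present in the PPI table; missing: "
            + ", ".join(sorted(core.members))
        )
    missing = sorted(core.members - present)
    node_set = set(present)
    for m in present:
        node_set.update(g.neighbors(m))
    if edges == "induced":
        kept = [r for r in ppi if r.a in node_set and r.b in node_set]
    else:
        kept = [r for r in ppi if r.a in present or r.b in present]
    net = InteractionNetwork.from_records(
        name,
        kept,
        extra_nodes=node_set,
        provenance={
            "rule": "direct",
            "edges": edges,
            "core": core.name,
            "core_missing_from_ppi": missing,
        },
    )
    logger.info(
        "%s: %d core seeds -> %d proteins, %d interactions",
        name,
        len(core),
        net.n_nodes,
        net.n_interactions,
    )
    return net


def build_induced_interactome(
    ppi: Sequence[InteractionRecord], seeds: ProteinSet, name: str | None = None
) -> InteractionNetwork:
    """Subnetwork of the PPI table induced on a curated seed list.

    Seeds not present anywhere in the PPI table are dropped from the network
    and listed in ``provenance["seeds_absent_from_ppi"]``.
    """
    if not seeds.members:
        raise EmptyInputError(f"seed set '{seeds.name}' is empty")
    if not ppi:
        raise EmptyInputError("PPI edge table is empty")
    g = _ppi_graph(ppi)
    present = {m for m in seeds.members if m in g}
    absent = sorted(seeds.members - present)
    kept = [r for r in ppi if r.a in present and r.b in present]
    net = InteractionNetwork.from_records(
        name or f"{seeds.name}I",
        kept,
        extra_nodes=present,
        provenance={
            "rule": "induced",
            "seeds": seeds.name,
            "n_seeds": len(seeds),
            "n_seeds_in_ppi": len(present),
            "seeds_absent_from_ppi": absent,
        },
    )
    if absent:
        logger.info(
            "%s: %d of %d seeds absent from the PPI table",
            net.name,
            len(absent),
            len(seeds),
        )
    return net


def union_networks(
    networks: Sequence[InteractionNetwork], name: str = "UNION"
) -> InteractionNetwork:
    """Node- and edge-wise union of two or more networks."""
    if len(networks) < 2:
        raise ValueError("union requires at least 2 networks")
    g = nx.Graph()
    for net in networks:
        g.add_nodes_from(net.graph.nodes)
        for a, b, data in net.graph.edges(data=True):
            srcs = frozenset(data.get("sources", ()))
            if g.has_edge(a, b):
                g.edges[a, b]["sources"] = g.edges[a, b]["sources"] | srcs
            else:
                g.add_edge(a, b, sources=srcs)
    return InteractionNetwork(
        name=name,
        graph=g,
        provenance={"rule": "union", "inputs": [n.name for n in networks]},
    )


def core_network(
    networks: Sequence[InteractionNetwork], name: str = "core"
) -> InteractionNetwork:
    """Intersection of node sets, with union edges restricted to it.

    An empty intersection yields an empty network with a warning, not an
    error.
    """
    if len(networks) < 2:
        raise ValueError("core requires at least 2 networks")
    shared = set(networks[0].graph.nodes)
    for net in networks[1:]:
        shared &= set(net.graph.nodes)
    union = union_networks(networks, name="_tmp_union")
    g = union.graph.subgraph(shared).copy()
    if not shared:
        warnings.warn("core network is empty: input node sets are disjoint")
    return InteractionNetwork(
        name=name,
        graph=g,
        provenance={"rule": "core", "inputs": [n.name for n in networks]},
    )


def component_summary(network: InteractionNetwork) -> ComponentSummary:
    """Component structure over non-self-loop edges.

    A node whose only incident edge is a self-loop counts as isolated. The
    main cluster is the largest component; among equal-size largest
    components the one containing the lexicographically smallest member wins
    (the edge count reported for it excludes self-loops).
    """
    g = network.simple_graph()
    comps = sorted(
        (sorted(c) for c in nx.connected_components(g)),
        key=lambda c: (-len(c), c[0]),
    )
    if not comps:
        return ComponentSummary(0, 0, 0, ())
    main = comps[0]
    main_edges = g.subgraph(main).number_of_edges()
    sizes = tuple(len(c) for c in comps)
    return ComponentSummary(
        main_cluster_size=len(main),
        main_cluster_edges=main_edges,
        isolated_count=sum(1 for s in sizes if s == 1),
        component_sizes=sizes,
    )
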