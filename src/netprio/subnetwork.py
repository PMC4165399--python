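"""Mapping DEGs onto a parent PPI network and extracting subnetworks.

Two extractions mirror the standard Cytoscape workflow: the *first-neighbor*
subnetwork is the induced subgraph on the mapped DEGs plus every node adjacent
to one of them in the parent (so neighbor–neighbor edges are kept), and the
*DEG–DEG* subnetwork is the induced subgraph on the mapped DEGs alone, with
isolated DEGs retained and flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .deg import DEGTable
from .network import PPINetwork, write_graphml, write_sif

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Subnetwork:
    """An extracted subgraph with per-node roles.

    ``annotation`` covers exactly the node set with labels from
    {"up", "down", "seed", "neighbor"}; ``isolated`` flags seed nodes that had
    no qualifying edge (only populated by the DEG–DEG extraction).
    """

    graph: PPINetwork
    seed_genes: frozenset[str]
    annotation: dict[str, str]
    isolated: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        assert set(self.annotation) == set(self.graph.nodes)

    def summary(self) -> dict[str, int]:
        return {
            "nodes": self.graph.number_of_nodes(),
            "edges": self.graph.number_of_edges(),
            "seeds": len(self.seed_genes & set(self.graph.nodes)),
            "isolated_seeds": len(self.isolated),
        }

    def write(self, prefix: str | Path) -> None:
        """SIF + node-attribute TSV (node, role) + GraphML under a path prefix."""
        prefix = Path(prefix)
        write_sif(self.graph, prefix.with_suffix(".sif"))
        with prefix.with_suffix(".nodes.tsv").open("w") as fh:
            fh.write("node\trole\n")
            for node in sorted(self.graph.nodes):
                fh.write(f"{node}\t{self.annotation[node]}\n")
        g = self.graph.copy()
        nx.set_node_attributes(g, self.annotation, "role")
        write_graphml(g, prefix.with_suffix(".graphml"))


def map_degs(parent: PPINetwork, degs: DEGTable | Iterable[str]) -> tuple[set[str], set[str]]:
    """Partition DEG symbols by membership in the parent node set."""
    symbols = degs.genes if isinstance(degs, DEGTable) else set(degs)
    mapped = symbols & set(parent.nodes)
    return mapped, symbols - mapped


def _roles(nodes: Iterable[str], seeds: frozenset[str],
           directions: Mapping[str, str] | None) -> dict[str, str]:
    directions = directions or {}
    return {
        n: (directions.get(n, "seed") if n in seeds else "neighbor") for n in nodes
    }


def first_neighbor_subnetwork(
    parent: PPINetwork,
    seeds: Iterable[str],
    directions: Mapping[str, str] | None = None,
) -> Subnetwork:
    """Induced subgraph on the seeds plus all their first neighbors.

    ``directions`` (gene -> up|down), typically ``DEGTable.directions``,
    annotates seed nodes; other nodes get the role "neighbor".  Seeds must
    already be mapped into the parent (use :func:`map_degs` first).
    """
    seeds = frozenset(seeds)
    missing = seeds - set(parent.nodes)
    if missing:
        raise KeyError(f"seeds not in parent network: {sorted(missing)[:10]}")
    if not seeds:
        log.warning("empty seed set -> empty subnetwork")
    nodes = set(seeds)
    for s in seeds:
        nodes.update(parent.neighbors(s))
    graph = nx.Graph(parent.subgraph(nodes))
    graph.graph["provenance"] = list(parent.graph.get("provenance", []))
    return Subnetwork(graph, seeds, _roles(graph.nodes, seeds, directions))


def deg_deg_subnetwork(
    parent: PPINetwork,
    seeds: Iterable[str],
    directions: Mapping[str, str] | None = None,
) -> Subnetwork:
    """Induced subgraph on the mapped DEGs only; isolated DEGs kept, flagged."""
    seeds = frozenset(seeds)
    missing = seeds - set(parent.nodes)
    if missing:
        raise KeyError(f"seeds not in parent network: {sorted(missing)[:10]}")
    graph = nx.Graph(parent.subgraph(seeds))
    graph.graph["provenance"] = list(parent.graph.get("provenance", []))
    isolated = frozenset(n for n in graph if graph.degree(n) == 0)
    return Subnetwork(graph, seeds, _roles(graph.nodes, seeds, directions), isolated)


def largest_component(sub: Subnetwork) -> Subnetwork:
    """The connected component with the most nodes.

    Ties are broken by the lexicographically smallest member symbol, so the
    result is deterministic.
    """
    if sub.graph.number_of_nodes() == 0:
        return sub
    best = min(nx.connected_components(sub.graph), key=lambda c: (-len(c), min(c)))
    graph = nx.Graph(sub.graph.subgraph(best))
    graph.graph["provenance"] = list(sub.graph.graph.get("provenance", []))
    return Subnetwork(
        graph,
        frozenset(s for s in sub.seed_genes if s in best),
        {n: sub.annotation[n] for n in graph.nodes},
        frozenset(n for n in sub.isolated if n in best),
    )
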