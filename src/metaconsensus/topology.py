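"""Substrate–product graph construction and topology metrics.

Compounds are nodes and reactions are edges: every substrate of a reaction is
connected to every product of that reaction by an undirected edge (reaction
directionality is generally ambiguous).  Parallel edges arising from several
reactions collapse to one; a compound appearing on both sides of a reaction
yields a self-loop; compounds participating in no reaction are left out.
Ubiquitous small molecules (ATP, NADH, water, ...) are deliberately kept.

Self-loops are excluded from node degrees and from the density and
average-connectivity identities (avg connectivity = 2(E−L)/N), and are
reported as a network-level count L.  Betweenness and closeness are
normalized within each connected component:

    C_b(n) = 2/((N−1)(N−2)) · Σ_{s<t} σ_st(n)/σ_st
    C_c(n) = (N−1) / Σ_m L(m, n)

with N the node count of n's component.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx

from .model_io import Reconstruction


@dataclass
class MetabolicGraph:
    """Undirected compound graph with tier colors and self-loop tracking."""

    g: nx.Graph

    @property
    def self_loop_count(self) -> int:
        return nx.number_of_selfloops(self.g)

    @property
    def node_count(self) -> int:
        return self.g.number_of_nodes()

    @property
    def edge_count(self) -> int:
        return self.g.number_of_edges()

    def simple(self) -> nx.Graph:
        """Copy without self-loops (used for paths, degree, clustering)."""
        h = self.g.copy()
        h.remove_edges_from(nx.selfloop_edges(h))
        return h

    def degrees(self) -> dict[str, int]:
        h = self.simple()
        return {n: d for n, d in h.degree()}


def build_graph(
    recon: Reconstruction, node_tiers: Mapping[str, str] | None = None
) -> MetabolicGraph:
    """Build the substrate–product graph of a reconstruction.

    ``node_tiers`` optionally maps local compound ids to tier colors
    (yellow/green/blue) stored as a node attribute.
    """
    recon.validate()
    g = nx.Graph()
    for rxn in recon.reactions.values():
        subs = [cid for cid, _ in rxn.substrates]
        prods = [cid for cid, _ in rxn.products]
        for s in subs:
            for p in prods:
                g.add_edge(s, p)
    if node_tiers:
        for n in g.nodes:
            g.nodes[n]["tier"] = node_tiers.get(n, "blue")
    return MetabolicGraph(g=g)


def betweenness(graph: MetabolicGraph) -> dict[str, float]:
    """Pair-normalized betweenness centrality, per connected component."""
    h = graph.simple()
    out: dict[str, float] = {}
    for comp in nx.connected_components(h):
        sub = h.subgraph(comp)
        if len(comp) <= 2:
            out.update({n: 0.0 for n in comp})
        else:
            out.update(nx.betweenness_centrality(sub, normalized=True))
    return out


def closeness(graph: MetabolicGraph) -> dict[str, float]:
    """Closeness within each component: (N−1)/Σ distances."""
    h = graph.simple()
    out: dict[str, float] = {}
    for comp in nx.connected_components(h):
        sub = h.subgraph(comp)
        if len(comp) == 1:
            out[next(iter(comp))] = 0.0
        else:
            out.update(nx.closeness_centrality(sub, wf_improved=False))
    return out


def clustering_coefficients(graph: MetabolicGraph) -> dict[str, float]:
    """Per-node clustering; degree-<2 nodes contribute 0."""
    return nx.clustering(graph.simple())


@dataclass
class TopologyReport:
    """Global metric panel plus per-node centralities and distributions."""

    node_count: int
    edge_count: int
    self_loop_count: int
    density: float
    heterogeneity: float
    clustering_coefficient: float
    connected_components: int
    diameter: int
    centralisation: float | None
    average_path_length: float
    average_connectivity: float
    degree: dict[str, int] = field(default_factory=dict)
    node_clustering: dict[str, float] = field(default_factory=dict)
    node_betweenness: dict[str, float] = field(default_factory=dict)
    node_closeness: dict[str, float] = field(default_factory=dict)
    degree_distribution: dict[int, int] = field(default_factory=dict)
    shared_neighbour_distribution: dict[int, int] = field(default_factory=dict)
    path_length_distribution: dict[int, int] = field(default_factory=dict)
    notes: dict[str, str] = field(default_factory=dict)

    def global_dict(self) -> dict:
        return {
            "number_of_nodes": self.node_count,
            "number_of_edges": self.edge_count,
            "network_density": self.density,
            "network_heterogeneity": self.heterogeneity,
            "number_of_self_loops": self.self_loop_count,
            "clustering_coefficient": self.clustering_coefficient,
            "connected_components": self.connected_components,
            "network_diameter": self.diameter,
            "network_centralisation": self.centralisation,
            "average_path_length": self.average_path_length,
            "average_connectivity": self.average_connectivity,
        }

    def to_json(self, path: str | Path) -> None:
        payload = self.global_dict()
        payload["distributions"] = {
            "degree": self.degree_distribution,
            "shared_neighbours": self.shared_neighbour_distribution,
            "shortest_path_length": self.path_length_distribution,
        }
        payload["notes"] = self.notes
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def global_metrics(graph: MetabolicGraph) -> TopologyReport:
    """Compute the full metric panel of the graph."""
    g = graph.g
    h = graph.simple()
    n = g.number_of_nodes()
    e = g.number_of_edges()
    loops = graph.self_loop_count
    degrees = {node: d for node, d in h.degree()}
    deg_values = list(degrees.values())
    mean_deg = sum(deg_values) / n if n else 0.0

    density = (2 * (e - loops) / (n * (n - 1))) if n > 1 else 0.0
    if mean_deg > 0:
        var = sum((d - mean_deg) ** 2 for d in deg_values) / n
        heterogeneity = math.sqrt(var) / mean_deg
    else:
        heterogeneity = 0.0

    clust = clustering_coefficients(graph)
    clustering_mean = sum(clust.values()) / n if n else 0.0

    components = list(nx.connected_components(h))
    diameter = 0
    path_dist: dict[int, int] = {}
    total_len = 0
    total_pairs = 0
    for comp in components:
        sub = h.subgraph(comp)
        for source, lengths in nx.all_pairs_shortest_path_length(sub):
            for target, dist in lengths.items():
                if source < target:  # unordered reachable pairs
                    path_dist[dist] = path_dist.get(dist, 0) + 1
                    total_len += dist
                    total_pairs += 1
                    diameter = max(diameter, dist)
    avg_path = total_len / total_pairs if total_pairs else 0.0

    if n > 2:
        centralisation = (n / (n - 2)) * (max(deg_values) / (n - 1) - density)
    else:
        centralisation = None

    deg_dist: dict[int, int] = {}
    for d in deg_values:
        deg_dist[d] = deg_dist.get(d, 0) + 1

    shared_dist: dict[int, int] = {}
    nodes = list(h.nodes)
    neigh = {node: set(h.neighbors(node)) for node in nodes}
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            k = len(neigh[u] & neigh[v])
            if k:
                shared_dist[k] = shared_dist.get(k, 0) + 1

    return TopologyReport(
        node_count=n,
        edge_count=e,
        self_loop_count=loops,
        density=density,
        heterogeneity=heterogeneity,
        clustering_coefficient=clustering_mean,
        connected_components=len(components),
        diameter=diameter,
        centralisation=centralisation,
        average_path_length=avg_path,
        average_connectivity=2 * (e - loops) / n if n else 0.0,
        degree=degrees,
        node_clustering=clust,
        node_betweenness=betweenness(graph),
        node_closeness=closeness(graph),
        degree_distribution=deg_dist,
        shared_neighbour_distribution=shared_dist,
        path_length_distribution=path_dist,
        notes={
            "clustering_convention": "nodes of degree < 2 contribute 0 to the mean",
            "self_loops": "excluded from degrees, density and average connectivity",
            "path_lengths": "computed over reachable pairs only",
        },
    )


def hub_table(graph: MetabolicGraph, top_k: int) -> list[tuple[str, int]]:
    """Top-degree nodes, ties broken lexicographically by id."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    degrees = graph.degrees()
    ranked = sorted(degrees.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:top_k]
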