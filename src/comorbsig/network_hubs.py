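"""Gene-network construction and degree-centrality hub detection.

Seed genes (a DEG signature) are combined with an undirected interaction
edge list into a graph whose nodes are tagged by role (seed_up, seed_down,
predicted).  Hubs are the top 20% of nodes by degree — the number of
distinct neighbors — with the count rounded up and ties at the cutoff broken
lexicographically so the selection is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .io_formats import EdgeList, ValidationError
from .signature_overlap import Signature

__all__ = ["GeneNetwork", "HubSet", "build_network", "select_hubs", "hub_table"]


@dataclass
class GeneNetwork:
    """Undirected gene graph with per-node role tags."""

    graph: nx.Graph

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def role(self, node: str) -> str:
        return self.graph.nodes[node]["role"]

    def degree(self, node: str, weighted: bool = False) -> float:
        if weighted:
            return float(self.graph.degree(node, weight="weight"))
        return int(self.graph.degree(node))

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


@dataclass
class HubSet:
    """Hub genes ordered by degree (descending), with the selection rule."""

    hubs: list[str]
    fraction: float
    cutoff_rank: int

    def __contains__(self, node: str) -> bool:
        return node in self.hubs

    def __len__(self) -> int:
        return len(self.hubs)


def build_network(seed_signature: Signature, edge_list: EdgeList) -> GeneNetwork:
    """Assemble the undirected graph of seeds plus interaction partners.

    Nodes are every gene appearing in the edge list plus isolated seeds;
    roles are seed_up / seed_down for signature genes and predicted for
    edge-introduced partners.  Duplicate edges and self-loops were already
    cleaned by :class:`EdgeList`.
    """
    graph = nx.Graph()
    for gene in sorted(seed_signature.up):
        graph.add_node(gene, role="seed_up")
    for gene in sorted(seed_signature.down):
        graph.add_node(gene, role="seed_down")
    for a, b, w in edge_list.edges:
        for node in (a, b):
            if node not in graph:
                graph.add_node(node, role="predicted")
        graph.add_edge(a, b, weight=w)
    if graph.number_of_nodes() == 0:
        raise ValidationError("network has no nodes (empty signature and edge list)")
    return GeneNetwork(graph)


def select_hubs(
    network: GeneNetwork, fraction: float = 0.2, weighted: bool = False
) -> HubSet:
    """Select the top ``fraction`` of nodes by degree as hubs.

    The hub count is ceil(fraction * n_nodes); nodes are ranked by degree
    descending with lexicographic gene-id tie-break.  ``weighted`` switches
    to strength (sum of edge weights) instead of neighbor count.
    """
    if not 0 < fraction <= 1:
        raise ValidationError("hub fraction must lie in (0, 1]")
    nodes = network.nodes
    if not nodes:
        raise ValidationError("cannot select hubs from an empty network")
    n_hubs = math.ceil(fraction * len(nodes))
    ranked = sorted(nodes, key=lambda n: (-network.degree(n, weighted=weighted), n))
    return HubSet(hubs=ranked[:n_hubs], fraction=fraction, cutoff_rank=n_hubs)


def hub_table(network: GeneNetwork, hub_set: HubSet) -> pd.DataFrame:
    """Per-node result table: node, role, degree, is_hub (degree-sorted)."""
    rows = sorted(network.nodes, key=lambda n: (-network.degree(n), n))
    return pd.DataFrame(
        {
            "node": rows,
            "role": [network.role(n) for n in rows],
            "degree": [network.degree(n) for n in rows],
            "is_hub": [n in hub_set.hubs for n in rows],
        }
    )
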