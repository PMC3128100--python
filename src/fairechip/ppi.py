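"""Expression-filtered first-order protein-interaction network construction.

Core proteins (human orthologs of differentially expressed knockout genes)
are expanded to their first-order interactors; interactors not detected as
expressed in megakaryocytes (detection P > 0.01) are removed; the largest
connected component of the induced graph is the reported network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .model import InteractionTable

__all__ = [
    "map_orthologs",
    "PPINetwork",
    "build_ppi_network",
    "network_summary",
]


def map_orthologs(gene_ids: Iterable[str],
                  ortholog_table: Mapping[str, str]) -> tuple[set[str], list[str]]:
    """Map gene ids to unique ortholog protein ids.

    Returns ``(core_protein_ids, dropped_gene_ids)``; genes without a
    mapping are reported, not fatal. Duplicate mappings collapse.
    """
    if not ortholog_table:
        raise ValueError("map_orthologs: empty ortholog table")
    mapped: set[str] = set()
    dropped: list[str] = []
    for gene in gene_ids:
        if gene in ortholog_table:
            mapped.add(ortholog_table[gene])
        else:
            dropped.append(gene)
    return mapped, dropped


@dataclass
class PPINetwork:
    """The retained largest connected component plus bookkeeping.

    ``graph`` nodes carry ``role`` ("core"/"interactor") and
    ``detection_p`` attributes. ``dropped_cores`` lists core proteins that
    did not make it into the component (no expressed first-order
    interactors, or disconnected); ``filtered_interactors`` those removed
    by the expression filter.
    """

    graph: nx.Graph
    core_ids: set[str]
    dropped_cores: list[str] = field(default_factory=list)
    filtered_interactors: list[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def retained_cores(self) -> set[str]:
        return {n for n in self.graph.nodes if self.graph.nodes[n]["role"] == "core"}


def _largest_component(graph: nx.Graph) -> set[str]:
    """Largest connected component; ties -> most edges, then smallest node set."""
    best: Optional[set[str]] = None
    best_key = None
    for comp in nx.connected_components(graph):
        comp = set(comp)
        key = (len(comp), graph.subgraph(comp).number_of_edges())
        if best is None or key > best_key or (key == best_key and sorted(comp) < sorted(best)):
            best, best_key = comp, key
    return best or set()


def build_ppi_network(core_ids: Iterable[str], interactions: InteractionTable,
                      detection_p: Mapping[str, float],
                      p_max: float = 0.01,
                      filter_cores: bool = False) -> PPINetwork:
    """Build the expression-filtered first-order network around core proteins.

    Candidate nodes are the cores plus every first-order interactor of a
    core; non-core interactors with detection P > ``p_max`` (or with no
    detection value) are removed; edges are induced on the survivors; only
    the largest connected component is retained. Cores are exempt from the
    expression filter unless ``filter_cores`` is set.
    """
    cores = set(core_ids)
    if not cores:
        raise ValueError("build_ppi_network: no core proteins")

    adjacency: dict[str, set[str]] = {}
    for a, b in interactions:
        adjacency.setdefault(a, set()).add(b)
        adjacency.setdefault(b, set()).add(a)

    interactors = set()
    for core in cores:
        interactors |= adjacency.get(core, set())
    interactors -= cores
    candidates = cores | interactors

    def expressed(node: str) -> bool:
        return detection_p.get(node, 1.0) <= p_max

    filtered = sorted(n for n in interactors if not expressed(n))
    if filter_cores:
        kept = {n for n in candidates if expressed(n)}
    else:
        kept = {n for n in candidates if n in cores or expressed(n)}

    graph = nx.Graph()
    graph.add_nodes_from(sorted(kept))
    for a, b in interactions:
        if a in kept and b in kept:
            graph.add_edge(a, b)

    lcc = _largest_component(graph)
    retained = graph.subgraph(sorted(lcc)).copy()
    for node in retained.nodes:
        retained.nodes[node]["role"] = "core" if node in cores else "interactor"
        retained.nodes[node]["detection_p"] = float(detection_p.get(node, 1.0))
    dropped_cores = sorted(cores - set(retained.nodes))
    return PPINetwork(retained, cores, dropped_cores, filtered)


def network_summary(net: PPINetwork) -> dict[str, float]:
    """Counts and degree statistics of the retained component."""
    degrees = [d for _, d in net.graph.degree()]
    return {
        "n_core_retained": len(net.retained_cores),
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "n_core_dropped": len(net.dropped_cores),
        "n_interactors_filtered": len(net.filtered_interactors),
        "mean_degree": float(sum(degrees) / len(degrees)) if degrees else 0.0,
        "max_degree": max(degrees) if degrees else 0,
    }
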