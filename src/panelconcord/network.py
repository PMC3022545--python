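"""Shortest-directed-path subnetworks over seed genes.

Given a curated directed interaction graph and a set of seed genes
(typically the differentially expressed candidates), the subnetwork is the
union of ALL shortest directed paths between ordered seed pairs, subject
to a path-length cap (default two edges, i.e. at most one intermediate
node). Unit edge weights make "shortest" mean fewest edges; keeping every
tied path makes the construction invariant to edge input order. Nodes are
then ranked by their total degree inside the subnetwork to expose hubs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .exceptions import ParameterError


@dataclass
class Subnetwork:
    graph: nx.DiGraph  # union of all retained paths, with edge attributes
    seeds: set
    paths: list  # (seed_from, seed_to, tuple of nodes along the path)
    unplaced: list  # seeds absent from the input graph, sorted

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set:
        return set(self.graph.edges)


def shortest_path_subnetwork(
    graph: nx.DiGraph, seeds, max_steps: int = 2
) -> Subnetwork:
    """All shortest directed paths of <= max_steps edges between seed pairs.

    Seeds missing from the graph are reported in ``unplaced`` rather than
    raising. Edge attributes (effect, mechanism) are carried over from the
    input graph.
    """
    if max_steps < 1:
        raise ParameterError(f"max_steps must be >= 1, got {max_steps}")
    seeds = set(seeds)
    if not seeds:
        raise ParameterError("seed set must be nonempty")
    placed = sorted(s for s in seeds if s in graph)
    unplaced = sorted(seeds - set(placed))
    sub = nx.DiGraph()
    paths = []
    for u in placed:
        # single-source BFS gives shortest-path lengths to every other seed
        lengths = nx.single_source_shortest_path_length(graph, u, cutoff=max_steps)
        for v in placed:
            if v == u or v not in lengths:
                continue
            for path in nx.all_shortest_paths(graph, u, v):
                paths.append((u, v, tuple(path)))
                nx.add_path(sub, path)
    for u, v in sub.edges:
        sub[u][v].update(graph[u][v])
    for node in sub.nodes:
        sub.nodes[node]["seed"] = node in seeds
    return Subnetwork(graph=sub, seeds=set(placed), paths=paths, unplaced=unplaced)


def hub_summary(subnetwork: Subnetwork) -> pd.DataFrame:
    """Nodes ranked by total (in+out) degree; ties broken lexicographically."""
    g = subnetwork.graph
    rows = [
        {
            "node": n,
            "degree": g.in_degree(n) + g.out_degree(n),
            "in_degree": g.in_degree(n),
            "out_degree": g.out_degree(n),
            "is_seed": n in subnetwork.seeds,
        }
        for n in g.nodes
    ]
    df = pd.DataFrame(rows, columns=["node", "degree", "in_degree", "out_degree", "is_seed"])
    if df.empty:
        return df
    return df.sort_values(["degree", "node"], ascending=[False, True]).reset_index(drop=True)
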