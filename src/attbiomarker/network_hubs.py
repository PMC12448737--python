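"""Degree-based hub ranking on a user-supplied interaction edge list.

Network construction (e.g. from STRING or NetworkAnalyst) is external;
this module ingests a two-column TSV or three-column SIF edge list,
normalizes it to a simple undirected graph (self-loops dropped,
duplicates collapsed), and ranks nodes by plain degree — the "Degree"
centrality of cytoHubba.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx

logger = logging.getLogger(__name__)


@dataclass
class EdgeList:
    """Simple undirected edge set with its implied vertex set."""

    edges: set[tuple[str, str]]
    node_ids: set[str]
    n_self_loops_dropped: int = 0

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        g.add_edges_from(self.edges)
        return g


def read_edge_list(path) -> EdgeList:
    """Parse a TSV (a<TAB>b) or SIF (a<TAB>relation<TAB>b) edge list.

    Undirected: a-b and b-a collapse; self-loops are dropped and
    counted. Malformed lines raise with their line number.
    """
    edges: set[tuple[str, str]] = set()
    nodes: set[str] = set()
    self_loops = 0
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) == 2:
                a, b = parts
            elif len(parts) == 3:  # SIF: relation column ignored
                a, _, b = parts
            else:
                raise ValueError(
                    f"line {lineno}: expected 2 (TSV) or 3 (SIF) columns, "
                    f"got {len(parts)}"
                )
            a, b = a.strip(), b.strip()
            if not a or not b:
                raise ValueError(f"line {lineno}: empty node id")
            n_lines += 1
            nodes.update((a, b))
            if a == b:
                self_loops += 1
                continue
            edges.add((min(a, b), max(a, b)))
    if n_lines == 0:
        warnings.warn("empty edge list", stacklevel=2)
    if self_loops:
        logger.info("dropped %d self-loop(s)", self_loops)
    return EdgeList(edges=edges, node_ids=nodes, n_self_loops_dropped=self_loops)


def top_hubs_by_degree(g: EdgeList, k: int = 10) -> list[tuple[str, int]]:
    """Top-k (node, degree) pairs; ties break by node id ascending."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    graph = g.to_graph()
    ranked = sorted(graph.degree(), key=lambda nd: (-nd[1], nd[0]))
    return [(n, int(d)) for n, d in ranked[:k]]
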