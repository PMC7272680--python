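"""Graph measures on binary adjacency matrices: node degree and density.

Graphs are undirected and simple.  Isolated regions are kept as nodes so
that density denominators stay comparable across groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .connectivity import BinaryAdjacency


@dataclass
class NetworkSummary:
    """Per-group summary of the two highlighted graph measures."""

    group: str
    degree: pd.Series
    n_edges: int
    density: float
    focal_region: str
    focal_degree: int

    def to_record(self) -> dict:
        return {
            "group": self.group,
            "n_regions": len(self.degree),
            "n_edges": self.n_edges,
            "density": self.density,
            "focal_region": self.focal_region,
            "focal_degree": self.focal_degree,
        }


def node_degree(adjacency: BinaryAdjacency) -> pd.Series:
    """Degree of every region: the number of incident edges."""
    deg = adjacency.matrix.sum(axis=1).astype(int)
    return pd.Series(deg, index=list(adjacency.regions), name="degree")


def network_density(adjacency: BinaryAdjacency) -> float:
    """Realized edges divided by the maximum possible, ``E / (N(N-1)/2)``."""
    n = adjacency.n_regions
    if n < 2:
        raise ValueError(f"network density requires at least 2 regions, got {n}")
    return adjacency.n_edges / (n * (n - 1) / 2)


def summarize(adjacency: BinaryAdjacency, group: str, focal_region: str) -> NetworkSummary:
    """Degree vector, edge count, density and focal-region degree."""
    if focal_region not in adjacency.regions:
        raise ValueError(f"focal region {focal_region!r} not among {adjacency.regions}")
    deg = node_degree(adjacency)
    return NetworkSummary(
        group=group,
        degree=deg,
        n_edges=adjacency.n_edges,
        density=network_density(adjacency),
        focal_region=focal_region,
        focal_degree=int(deg[focal_region]),
    )


def export_graph(adjacency: BinaryAdjacency, highlight: str) -> pd.DataFrame:
    """Undirected edge list with edges incident to ``highlight`` flagged.

    Returns a DataFrame with columns ``region_a``, ``region_b`` and
    ``focal_incident`` (bool), one row per edge, ``region_a`` preceding
    ``region_b`` in the adjacency's region order.
    """
    if highlight not in adjacency.regions:
        raise ValueError(f"unknown highlight region {highlight!r}")
    rows = []
    regions = adjacency.regions
    a = adjacency.matrix
    for i in range(len(regions)):
        for j in range(i + 1, len(regions)):
            if a[i, j]:
                rows.append(
                    {
                        "region_a": regions[i],
                        "region_b": regions[j],
                        "focal_incident": highlight in (regions[i], regions[j]),
                    }
                )
    return pd.DataFrame(rows, columns=["region_a", "region_b", "focal_incident"])


def adjacency_from_edges(edges: pd.DataFrame, regions: tuple[str, ...]) -> BinaryAdjacency:
    """Rebuild an adjacency from an exported edge list (exact round trip)."""
    index = {r: i for i, r in enumerate(regions)}
    a = np.zeros((len(regions), len(regions)), dtype=np.int8)
    for _, row in edges.iterrows():
        i, j = index[row["region_a"]], index[row["region_b"]]
        a[i, j] = a[j, i] = 1
    return BinaryAdjacency(tuple(regions), a)


def to_networkx(adjacency: BinaryAdjacency, highlight: str | None = None) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(adjacency.regions)
    edges = export_graph(adjacency, highlight or adjacency.regions[0])
    for _, row in edges.iterrows():
        g.add_edge(row["region_a"], row["region_b"], focal_incident=bool(row["focal_incident"]))
    return g


def write_graphml(adjacency: BinaryAdjacency, path, highlight: str | None = None) -> None:
    """Write a GraphML file for external graph viewers."""
    nx.write_graphml(to_networkx(adjacency, highlight), path)
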