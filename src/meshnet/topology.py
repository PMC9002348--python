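"""Per-node and global topology statistics for semantic networks.

Degree k is the unweighted count of adjacent concepts — for a term annotated
on every article this equals |V| − 1, the hallmark of the near-universal
"Humans" tag.  Rank R orders nodes by descending degree; ties are broken by
ascending label so that the ranking is a deterministic bijection onto
1..|V| regardless of node insertion order.  Centralities use standard
unweighted shortest-path definitions (closeness is Wasserman–Faust scaled by
component fraction on disconnected graphs; an isolated node has closeness 0).
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["NodeStat", "TopologyReport", "compute_node_stats", "top_ranked", "core_periphery"]


@dataclass(frozen=True)
class NodeStat:
    label: str
    k: int
    R: int
    strength: int
    betweenness: float
    closeness: float
    clustering: float


@dataclass
class TopologyReport:
    nodes: list[NodeStat]  # sorted by R
    n_nodes: int
    n_edges: int
    density: float
    n_components: int
    mean_clustering: float
    degree_histogram: dict[int, int]

    def global_stats(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "density": self.density,
            "n_components": self.n_components,
            "mean_clustering": self.mean_clustering,
            "degree_histogram": {str(k): v for k, v in sorted(self.degree_histogram.items())},
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(n) for n in self.nodes])

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6g")

    def write_global_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.global_stats(), fh, indent=2)
            fh.write("\n")


def compute_node_stats(net: nx.Graph) -> TopologyReport:
    """Compute the full per-node table and global statistics for *net*."""
    if net.number_of_nodes() == 0:
        raise ValueError("cannot compute statistics of an empty network")

    degree = dict(net.degree())
    strength = dict(net.degree(weight="weight"))
    betweenness = nx.betweenness_centrality(net, normalized=True)
    closeness = nx.closeness_centrality(net)
    clustering = nx.clustering(net)

    order = sorted(net.nodes, key=lambda v: (-degree[v], str(v)))
    nodes = [
        NodeStat(
            label=str(v),
            k=int(degree[v]),
            R=rank,
            strength=int(strength[v]),
            betweenness=float(betweenness[v]),
            closeness=float(closeness[v]),
            clustering=float(clustering[v]),
        )
        for rank, v in enumerate(order, start=1)
    ]
    n = net.number_of_nodes()
    return TopologyReport(
        nodes=nodes,
        n_nodes=n,
        n_edges=net.number_of_edges(),
        density=float(nx.density(net)),
        n_components=nx.number_connected_components(net),
        mean_clustering=float(nx.average_clustering(net)) if n > 1 else 0.0,
        degree_histogram=dict(Counter(degree.values())),
    )


def top_ranked(report: TopologyReport, n: int) -> list[NodeStat]:
    """The first min(n, |V|) nodes by rank (e.g. a Top-20 table)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return report.nodes[:n]


def core_periphery(report: TopologyReport, quantile: float) -> dict[str, str]:
    """Label each node ``core`` or ``periphery`` by a degree quantile cut.

    The top *quantile* fraction of nodes by degree (degree ≥ the empirical
    (1 − quantile) degree quantile) is the core.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError(f"quantile must be in (0, 1), got {quantile}")
    ks = np.array([ns.k for ns in report.nodes])
    threshold = float(np.quantile(ks, 1.0 - quantile))
    return {ns.label: ("core" if ns.k >= threshold else "periphery") for ns in report.nodes}
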