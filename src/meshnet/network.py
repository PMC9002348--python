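"""Semantic-network construction from a corpus.

The underlying structure is bipartite: articles on one side, MeSH concepts
on the other, with a membership for every (article, concept) annotation.
Two one-mode weighted projections follow:

* **concept projection** — the semantic network proper.  Two concepts are
  linked whenever some article is annotated with both; the edge weight is
  the number of such articles (co-occurrence count).
* **article projection** — articles linked by shared concepts; the more
  annotations two articles share, the heavier the edge.

Both projections satisfy a conservation law: the total edge weight of the
concept projection equals Σₐ C(tₐ, 2) over articles a with tₐ distinct
concepts (and dually for the article projection).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Hashable

import networkx as nx

from .corpus import Corpus
from .mesh_model import label

__all__ = [
    "BipartiteGraph",
    "build_bipartite",
    "project_concepts",
    "project_articles",
    "filter_min_weight",
    "write_edge_list",
    "write_graphml",
]


@dataclass
class BipartiteGraph:
    """Article–concept incidence structure."""

    articles: set[int] = field(default_factory=set)
    concepts: set[str] = field(default_factory=set)
    memberships: set[tuple[int, str]] = field(default_factory=set)


def build_bipartite(corpus: Corpus, mode: str = "distinct") -> BipartiteGraph:
    """Build the article–concept bipartite graph under a label mode.

    Identical labels within one record (possible under ``merged`` mode)
    collapse to a single membership.
    """
    bip = BipartiteGraph()
    for rec in corpus.records:
        bip.articles.add(rec.pmid)
        for ent in rec.entities:
            lab = label(ent, mode)
            bip.concepts.add(lab)
            bip.memberships.add((rec.pmid, lab))
    return bip


def _grouped(bip: BipartiteGraph, by_article: bool) -> dict[Hashable, set]:
    groups: dict[Hashable, set] = defaultdict(set)
    for pmid, lab in bip.memberships:
        if by_article:
            groups[pmid].add(lab)
        else:
            groups[lab].add(pmid)
    return groups


def _project(sides: dict[Hashable, set], all_nodes) -> nx.Graph:
    weights: Counter = Counter()
    for members in sides.values():
        for a, b in combinations(sorted(members, key=str), 2):
            weights[(a, b)] += 1
    g = nx.Graph()
    g.add_nodes_from(all_nodes)
    g.add_weighted_edges_from((a, b, w) for (a, b), w in weights.items())
    return g


def project_concepts(bip: BipartiteGraph) -> nx.Graph:
    """Concept co-occurrence projection (the semantic network).

    Nodes are all concept labels with at least one membership; edge weight is
    the number of articles annotated with both endpoints.
    """
    return _project(_grouped(bip, by_article=True), sorted(bip.concepts))


def project_articles(bip: BipartiteGraph) -> nx.Graph:
    """Article similarity projection: edge weight = number of shared labels."""
    return _project(_grouped(bip, by_article=False), sorted(bip.articles))


def filter_min_weight(net: nx.Graph, min_weight: int) -> nx.Graph:
    """Copy of *net* without edges lighter than *min_weight* (nodes kept)."""
    out = net.copy()
    out.remove_edges_from(
        [(a, b) for a, b, w in net.edges(data="weight") if w < min_weight]
    )
    return out


def write_edge_list(net: nx.Graph, path: str | Path) -> None:
    """Write a sorted ``source<TAB>target<TAB>weight`` edge list."""
    rows = sorted((str(a), str(b), int(w)) for a, b, w in net.edges(data="weight"))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tweight\n")
        for a, b, w in rows:
            fh.write(f"{a}\t{b}\t{w}\n")


def write_graphml(net: nx.Graph, path: str | Path) -> None:
    """GraphML export for graph-visualization tools (Cytoscape, Gephi)."""
    nx.write_graphml(net, path)
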