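"""Seed-and-first-neighbor (ego) subnetwork extraction.

Thematic subnetworks are built from a set of seed concepts: take the seeds,
add every node within graph distance ``radius`` (default 1, i.e. the first
neighbors), and keep the *induced* subgraph — every parent edge between two
retained nodes survives, with its weight.  This is what makes the extracted
themes dense: neighbor–neighbor edges are kept, not just seed-incident ones.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field

import networkx as nx

__all__ = ["SeedSpec", "SeedNotFoundError", "extract_subnetwork", "subnetwork_summary"]


@dataclass(frozen=True)
class SeedSpec:
    seeds: frozenset[str]
    radius: int = 1
    include_major_variants: bool = False

    def __post_init__(self) -> None:
        if not self.seeds:
            raise ValueError("at least one seed label is required")
        if self.radius < 1:
            raise ValueError("radius must be >= 1")

    @classmethod
    def of(cls, *seeds: str, radius: int = 1, include_major_variants: bool = False) -> "SeedSpec":
        return cls(frozenset(seeds), radius, include_major_variants)


class SeedNotFoundError(KeyError):
    """A seed label is absent from the network; carries nearest-label hints."""

    def __init__(self, seed: str, suggestions: list[str]):
        self.seed = seed
        self.suggestions = suggestions
        hint = f"; did you mean {', '.join(repr(s) for s in suggestions)}?" if suggestions else ""
        super().__init__(f"seed label {seed!r} not in network{hint}")

    def __str__(self) -> str:  # KeyError would repr() the message
        return self.args[0]


def extract_subnetwork(net: nx.Graph, spec: SeedSpec) -> nx.Graph:
    """Induced subgraph on the seeds and everything within ``spec.radius``.

    With ``include_major_variants`` the asterisked twin of each seed (e.g.
    ``*Culture`` for ``Culture``) is also used as a seed when present; unlike
    the seeds themselves, a missing variant is not an error.
    """
    seeds = set(spec.seeds)
    for seed in spec.seeds:
        if seed not in net:
            close = difflib.get_close_matches(seed, [str(v) for v in net.nodes], n=3)
            raise SeedNotFoundError(seed, close)
        if spec.include_major_variants:
            variant = seed[1:] if seed.startswith("*") else "*" + seed
            if variant in net:
                seeds.add(variant)

    keep: set = set(seeds)
    for seed in seeds:
        keep.update(nx.single_source_shortest_path_length(net, seed, cutoff=spec.radius))
    return net.subgraph(keep).copy()


def subnetwork_summary(sub: nx.Graph) -> tuple[int, int]:
    """(node count, edge count) of a subnetwork, as reported in figures."""
    return sub.number_of_nodes(), sub.number_of_edges()
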