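"""MMP network construction and analog-series extraction.

Compounds are nodes; an edge joins two compounds that form at least one
MMP, and carries the set of all canonical cores shared by the pair.  Each
connected component of the network is one analog series.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from asbscaffolds.chem_core import Fragment
from asbscaffolds.mmp_engine import MMP

__all__ = ["AnalogSeries", "build_network", "extract_series"]


@dataclass(frozen=True)
class AnalogSeries:
    """A connected component of the MMP network (>= 2 compounds)."""

    series_id: str
    members: frozenset[str]
    #: unordered member pair -> frozenset of shared cores
    edges: dict[tuple[str, str], frozenset[Fragment]]

    @property
    def size(self) -> int:
        return len(self.members)

    def degree(self, compound_id: str) -> int:
        return sum(1 for e in self.edges if compound_id in e)

    def edge_cores(self, a: str, b: str) -> frozenset[Fragment]:
        """Cores shared by a member pair (empty frozenset if no edge)."""
        key = (a, b) if a < b else (b, a)
        return self.edges.get(key, frozenset())


def build_network(mmps: list[MMP]) -> nx.Graph:
    """One node per compound in any MMP; one edge per pair, with all cores.

    Several MMP records between the same pair (distinct cores) collapse to
    a single edge whose ``cores`` attribute accumulates every shared core.
    """
    g = nx.Graph()
    for mmp in mmps:
        a, b = mmp.compound_a, mmp.compound_b
        if a == b:
            raise ValueError(f"self-loop MMP for compound {a!r}")
        if g.has_edge(a, b):
            g.edges[a, b]["cores"].add(mmp.core)
        else:
            g.add_edge(a, b, cores={mmp.core})
    return g


def extract_series(network: nx.Graph) -> list[AnalogSeries]:
    """Connected components as analog series, deterministically ordered.

    Components are sorted by their smallest member identifier and numbered
    S0001, S0002, ...; every node of the network belongs to exactly one
    series (nodes only arise from MMPs, so no singletons exist).
    """
    components = sorted(
        (sorted(comp) for comp in nx.connected_components(network)),
        key=lambda members: members[0],
    )
    series: list[AnalogSeries] = []
    width = max(4, len(str(len(components))))
    for i, members in enumerate(components, start=1):
        sub = network.subgraph(members)
        edges = {
            (a, b) if a < b else (b, a): frozenset(data["cores"])
            for a, b, data in sub.edges(data=True)
        }
        series.append(
            AnalogSeries(
                series_id=f"S{i:0{width}d}",
                members=frozenset(members),
                edges=edges,
            )
        )
    return series
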