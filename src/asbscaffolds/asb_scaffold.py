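"""Structural-key compounds, qualifying cores, ASB scaffolds and core covers.

A structural-key (SK) compound of an analog series forms an MMP with every
other member.  A qualifying core is an MMP core of an SK compound that
backs an MMP relationship to every other analog; the largest qualifying
core (by heavy atoms) is the analog series-based (ASB) scaffold.  When no
single core qualifies, a minimum set of SK-compound cores jointly covering
all members is computed instead.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

from asbscaffolds.chem_core import Fragment
from asbscaffolds.mmp_engine import MMP
from asbscaffolds.series_network import AnalogSeries

logger = logging.getLogger(__name__)

__all__ = [
    "ASBScaffold",
    "CoreCover",
    "SKAssignment",
    "compute_core_cover",
    "find_sk_compounds",
    "qualifying_cores",
    "select_asb_scaffold",
]


@dataclass(frozen=True)
class SKAssignment:
    series_id: str
    sk_compounds: frozenset[str]


@dataclass(frozen=True)
class ASBScaffold:
    """The series scaffold: largest qualifying core of an SK compound."""

    series_id: str
    core: Fragment
    source_sk: str
    covered_members: frozenset[str]
    heavy_atoms: int


@dataclass(frozen=True)
class CoreCover:
    """A minimum set of SK cores jointly spanning a series without a scaffold."""

    series_id: str
    cores: tuple[Fragment, ...]
    size: int
    method: str  # "exact" or "greedy"


def find_sk_compounds(series: AnalogSeries) -> SKAssignment:
    """Members with MMP edges to all other members (degree = size - 1)."""
    full = series.size - 1
    sk = frozenset(m for m in series.members if series.degree(m) == full)
    return SKAssignment(series.series_id, sk)


def qualifying_cores(
    series: AnalogSeries, sk: SKAssignment
) -> list[tuple[Fragment, str]]:
    """Cores of SK compounds that back an MMP to every other series member.

    Pooled across all SK compounds; duplicates collapse by canonical core,
    attributed to the smallest SK compound identifier that owns the core.
    Returns (core, source_sk) sorted by core.
    """
    found: dict[Fragment, str] = {}
    for s in sorted(sk.sk_compounds):
        others = series.members - {s}
        if not others:
            continue
        shared = None
        for m in others:
            cores = series.edge_cores(s, m)
            shared = cores if shared is None else shared & cores
            if not shared:
                break
        for core in shared or ():
            found.setdefault(core, s)
    return sorted(found.items())


def select_asb_scaffold(
    candidates: list[tuple[Fragment, str]], series: AnalogSeries
) -> ASBScaffold | None:
    """Largest qualifying core by heavy atoms; ties broken lexicographically.

    None iff there is no qualifying core.
    """
    if not candidates:
        return None
    core, source = min(candidates, key=lambda cs: (-cs[0].heavy_atoms, cs[0].structure))
    return ASBScaffold(
        series_id=series.series_id,
        core=core,
        source_sk=source,
        covered_members=series.members,
        heavy_atoms=core.heavy_atoms,
    )


def _candidate_covers(
    series: AnalogSeries, sk: SKAssignment
) -> dict[Fragment, frozenset[str]]:
    """Per SK core: the member set it covers (the SK compound + its MMP partners)."""
    coverage: dict[Fragment, set[str]] = {}
    for s in sorted(sk.sk_compounds):
        for m in series.members - {s}:
            for core in series.edge_cores(s, m):
                coverage.setdefault(core, set()).update((s, m))
    return {core: frozenset(members) for core, members in coverage.items()}


def compute_core_cover(
    series: AnalogSeries,
    sk: SKAssignment,
    exact_threshold: int = 20,
) -> CoreCover | None:
    """Minimum-cardinality set of SK cores whose coverage spans the series.

    Exact minimum by enumeration when there are at most ``exact_threshold``
    candidate cores, greedy set cover beyond that (flagged in ``method``).
    Intended for series with SK compounds but no single qualifying core;
    returns None if even the union of all SK cores misses some member
    (impossible when SK compounds exist, kept as a defensive branch).
    """
    if not sk.sk_compounds:
        return None
    coverage = _candidate_covers(series, sk)
    universe = series.members
    if set().union(*coverage.values(), frozenset()) != universe:
        logger.warning("series %s: SK cores do not span all members", series.series_id)
        return None
    cores_sorted = sorted(coverage, key=lambda c: (-len(coverage[c]), c.structure))

    if len(cores_sorted) <= exact_threshold:
        for k in range(1, len(cores_sorted) + 1):
            for combo in itertools.combinations(cores_sorted, k):
                covered = frozenset().union(*(coverage[c] for c in combo))
                if covered == universe:
                    return CoreCover(series.series_id, tuple(sorted(combo)), k, "exact")
        return None  # unreachable: the full set spans the universe

    chosen: list[Fragment] = []
    remaining = set(universe)
    while remaining:
        best = min(
            cores_sorted, key=lambda c: (-len(coverage[c] & remaining), c.structure)
        )
        if not coverage[best] & remaining:
            return None
        chosen.append(best)
        remaining -= coverage[best]
    return CoreCover(series.series_id, tuple(sorted(chosen)), len(chosen), "greedy")
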