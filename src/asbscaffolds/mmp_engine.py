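"""Size-constrained RECAP matched-molecular-pair generation.

An MMP is an unordered pair of compounds that share an identical canonical
single-cut core and differ only in the exchanged substituent.  The fragment
size restrictions keep pairs to typical analogs: the larger exchanged
substituent may have at most 13 heavy atoms and the conserved core must be
at least twice the size of the larger substituent.

Generation is core-indexed: fragment pairs from all compounds are grouped
by canonical core string, so that candidate pairs are only enumerated
within a shared-core bucket.  This is equivalent to brute-force all-pairs
comparison (two compounds form an MMP iff some bucket contains them both
with different substituents) but linear in the total number of fragment
pairs.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass

from asbscaffolds.chem_core import Compound, Fragment, FragmentPair, RuleSet, enumerate_recap_cuts

__all__ = ["MMP", "MMPConstraints", "check_constraints", "generate_mmps", "mmps_from_fragment_pairs"]


@dataclass(frozen=True)
class MMPConstraints:
    """Fragment size restrictions for analog-like MMPs."""

    max_substituent_heavy_atoms: int = 13
    core_to_substituent_ratio: float = 2.0

    def __post_init__(self) -> None:
        if self.max_substituent_heavy_atoms < 1:
            raise ValueError("max_substituent_heavy_atoms must be >= 1")
        if self.core_to_substituent_ratio <= 0:
            raise ValueError("core_to_substituent_ratio must be positive")


@dataclass(frozen=True)
class MMP:
    """A matched molecular pair: unordered compounds + shared core.

    ``compound_a < compound_b`` by identifier, for determinism.
    """

    compound_a: str
    compound_b: str
    core: Fragment
    substituent_a: Fragment
    substituent_b: Fragment
    rule_id: str


def check_constraints(
    core: Fragment, sub_a: Fragment, sub_b: Fragment, constraints: MMPConstraints | None = None
) -> bool:
    """True iff the pair satisfies the analog-size restrictions.

    The larger substituent must have at most ``max_substituent_heavy_atoms``
    heavy atoms, and the core at least ``core_to_substituent_ratio`` times
    the larger substituent's heavy atoms.
    """
    c = constraints or MMPConstraints()
    larger = max(sub_a.heavy_atoms, sub_b.heavy_atoms)
    if larger > c.max_substituent_heavy_atoms:
        return False
    return core.heavy_atoms >= c.core_to_substituent_ratio * larger


def _emit_pairs(
    buckets: dict[Fragment, dict[str, set[tuple[Fragment, str]]]],
    constraints: MMPConstraints,
) -> list[MMP]:
    """Turn core buckets into deduplicated, constraint-checked MMP records.

    One record per (pair, core); if a pair shares a core through several
    substituent combinations, the lexicographically smallest combination is
    kept.
    """
    chosen: dict[tuple[str, str, Fragment], tuple[Fragment, Fragment, str]] = {}
    for core, per_compound in buckets.items():
        if len(per_compound) < 2:
            continue
        for id_a, id_b in itertools.combinations(sorted(per_compound), 2):
            for (sub_a, rule_a), (sub_b, rule_b) in itertools.product(
                sorted(per_compound[id_a]), sorted(per_compound[id_b])
            ):
                if sub_a == sub_b:
                    continue
                if not check_constraints(core, sub_a, sub_b, constraints):
                    continue
                key = (id_a, id_b, core)
                cand = (sub_a, sub_b, rule_a)
                if key not in chosen or cand < chosen[key]:
                    chosen[key] = cand
    return sorted(
        (
            MMP(a, b, core, sub_a, sub_b, rule)
            for (a, b, core), (sub_a, sub_b, rule) in chosen.items()
        ),
        key=lambda m: (m.compound_a, m.compound_b, m.core.structure),
    )


def generate_mmps(
    compounds: list[Compound],
    rules: RuleSet,
    constraints: MMPConstraints | None = None,
) -> list[MMP]:
    """All size-constrained MMPs over a deduplicated compound set."""
    constraints = constraints or MMPConstraints()
    pairs: list[FragmentPair] = []
    for comp in compounds:
        pairs.extend(enumerate_recap_cuts(comp, rules))
    return mmps_from_fragment_pairs(pairs, constraints)


def mmps_from_fragment_pairs(
    fragment_pairs: list[FragmentPair], constraints: MMPConstraints | None = None
) -> list[MMP]:
    """Core-indexed MMP assembly from precomputed fragment pairs."""
    constraints = constraints or MMPConstraints()
    buckets: dict[Fragment, dict[str, set[tuple[Fragment, str]]]] = defaultdict(
        lambda: defaultdict(set)
    )
    for fp in fragment_pairs:
        buckets[fp.core][fp.parent_id].add((fp.substituent, fp.rule_id))
    return _emit_pairs(buckets, constraints)


def generate_mmps_bruteforce(
    compounds: list[Compound],
    rules: RuleSet,
    constraints: MMPConstraints | None = None,
) -> list[MMP]:
    """O(n^2) reference generator: compare every compound pair directly.

    Exists as an independent check of the core-indexed path; identical
    output contract, quadratic cost.
    """
    constraints = constraints or MMPConstraints()
    cuts = {c.compound_id: enumerate_recap_cuts(c, rules) for c in compounds}
    chosen: dict[tuple[str, str, Fragment], tuple[Fragment, Fragment, str]] = {}
    for ca, cb in itertools.combinations(sorted(compounds, key=lambda c: c.compound_id), 2):
        for fp_a in sorted(cuts[ca.compound_id], key=lambda f: (f.core, f.substituent)):
            for fp_b in sorted(cuts[cb.compound_id], key=lambda f: (f.core, f.substituent)):
                if fp_a.core != fp_b.core or fp_a.substituent == fp_b.substituent:
                    continue
                if not check_constraints(fp_a.core, fp_a.substituent, fp_b.substituent, constraints):
                    continue
                key = (ca.compound_id, cb.compound_id, fp_a.core)
                cand = (fp_a.substituent, fp_b.substituent, fp_a.rule_id)
                if key not in chosen or cand < chosen[key]:
                    chosen[key] = cand
    return sorted(
        (
            MMP(a, b, core, sub_a, sub_b, rule)
            for (a, b, core), (sub_a, sub_b, rule) in chosen.items()
        ),
        key=lambda m: (m.compound_a, m.compound_b, m.core.structure),
    )
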