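"""High-confidence activity-data selection and potency aggregation.

Only equilibrium constants (Ki) and IC50 values measured as exact values
("=" relation) against single human protein targets at the highest assay
confidence are retained.  Multiple measurements for the same compound,
target and measurement type are combined into one potency annotation as
their geometric mean, provided they all fall within the same order of
magnitude; otherwise the pair is discarded as irreproducible.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field

from asbscaffolds import chem_core
from asbscaffolds.chem_core import Compound, StructureError

__all__ = [
    "ActivityRecord",
    "AnnotatedCompound",
    "CurationConfig",
    "PotencyAnnotation",
    "aggregate_potency",
    "build_compound_set",
    "filter_records",
]

#: multiply a value in the given unit by this factor to express it in nM
UNIT_TO_NM = {
    "M": 1e9,
    "mM": 1e6,
    "uM": 1e3,
    "µM": 1e3,
    "um": 1e3,
    "nM": 1.0,
    "pM": 1e-3,
}


@dataclass(frozen=True)
class ActivityRecord:
    """One raw activity measurement, as exported from a bioactivity database."""

    compound_id: str
    smiles: str
    target_id: str
    target_organism: str
    relationship_type: str
    confidence_score: int
    measurement_type: str  # e.g. "Ki", "IC50"
    relation: str  # "=", ">", "<", "~", ">=", "<="
    value: float
    unit: str


@dataclass(frozen=True)
class PotencyAnnotation:
    """Final potency of a compound against one target (geometric mean, nM)."""

    compound_id: str
    target_id: str
    measurement_type: str
    potency_nM: float
    n_measurements: int


@dataclass
class CurationConfig:
    """Record-retention criteria.

    Defaults select direct single-protein interactions (relationship type
    'D') with human targets at confidence score 9, exact Ki/IC50 values
    convertible to nM, and cap the within-pair dynamic range at one order
    of magnitude (max/min <= 10) for geometric-mean aggregation.
    """

    relationship_type: str = "D"
    confidence_score: int = 9
    organism: str = "Homo sapiens"
    measurement_types: tuple[str, ...] = ("Ki", "IC50")
    max_value_ratio: float = 10.0
    unit_to_nM: dict = field(default_factory=lambda: dict(UNIT_TO_NM))


def filter_records(
    records: list[ActivityRecord], criteria: CurationConfig | None = None
) -> tuple[list[ActivityRecord], Counter]:
    """Apply the high-confidence selection filters.

    Returns the retained records (values converted to nM) and a Counter of
    rejection reasons.  Approximate qualifiers ('>', '<', '~', '>=', '<=')
    are discarded; only '=' survives.
    """
    criteria = criteria or CurationConfig()
    kept: list[ActivityRecord] = []
    reasons: Counter = Counter()
    for rec in records:
        if rec.relationship_type != criteria.relationship_type:
            reasons["relationship_type"] += 1
        elif rec.confidence_score != criteria.confidence_score:
            reasons["confidence_score"] += 1
        elif rec.target_organism != criteria.organism:
            reasons["organism"] += 1
        elif rec.measurement_type not in criteria.measurement_types:
            reasons["measurement_type"] += 1
        elif rec.relation != "=":
            reasons["approximate_relation"] += 1
        elif rec.unit not in criteria.unit_to_nM:
            reasons["unknown_unit"] += 1
        elif not (rec.value > 0):
            reasons["nonpositive_value"] += 1
        else:
            factor = criteria.unit_to_nM[rec.unit]
            kept.append(
                ActivityRecord(
                    compound_id=rec.compound_id,
                    smiles=rec.smiles,
                    target_id=rec.target_id,
                    target_organism=rec.target_organism,
                    relationship_type=rec.relationship_type,
                    confidence_score=rec.confidence_score,
                    measurement_type=rec.measurement_type,
                    relation="=",
                    value=rec.value * factor,
                    unit="nM",
                )
            )
    return kept, reasons


def aggregate_potency(
    values: list[float], max_ratio: float = 10.0
) -> float | None:
    """Geometric mean of same-pair potency values (nM), or None to discard.

    The values must all fall within the same order of magnitude
    (max/min <= ``max_ratio``); otherwise the measurements are considered
    inconsistent and the compound-target pair contributes no annotation.
    """
    if not values:
        raise ValueError("aggregate_potency requires at least one value")
    if any(v <= 0 for v in values):
        raise ValueError("potency values must be positive")
    if max(values) / min(values) > max_ratio:
        return None
    if len(values) == 1:
        return float(values[0])
    return math.exp(sum(math.log(v) for v in values) / len(values))


@dataclass
class AnnotatedCompound:
    """A unique structure plus its per-target potency annotations."""

    compound: Compound
    annotations: list[PotencyAnnotation]

    @property
    def target_ids(self) -> set[str]:
        return {a.target_id for a in self.annotations}


def build_compound_set(
    records: list[ActivityRecord],
    criteria: CurationConfig | None = None,
) -> tuple[list[AnnotatedCompound], Counter]:
    """Filtered records -> deduplicated compounds with potency annotations.

    Structures are salt-stripped, canonicalized and deduplicated by
    canonical SMILES; per compound-target-type groups the geometric-mean
    rule of :func:`aggregate_potency` is applied.  Compounds whose every
    group is discarded (or whose structure fails to parse) are dropped,
    with counts per reason.
    """
    criteria = criteria or CurationConfig()
    kept, reasons = filter_records(records, criteria)

    # canonical structure per source compound_id; ids sharing a structure merge
    by_structure: dict[str, dict] = {}
    id_to_structure: dict[str, str] = {}
    for rec in kept:
        if rec.compound_id in id_to_structure:
            continue
        try:
            canon = chem_core.canonicalize(
                chem_core.strip_to_largest_component(rec.smiles)
            )
        except StructureError:
            reasons["structure_parse_failure"] += 1
            id_to_structure[rec.compound_id] = ""
            continue
        id_to_structure[rec.compound_id] = canon
        entry = by_structure.setdefault(canon, {"ids": []})
        entry["ids"].append(rec.compound_id)

    # group measurements by (structure, target, type)
    groups: dict[tuple[str, str, str], list[float]] = defaultdict(list)
    for rec in kept:
        canon = id_to_structure.get(rec.compound_id, "")
        if not canon:
            continue
        groups[(canon, rec.target_id, rec.measurement_type)].append(rec.value)

    annotations_by_structure: dict[str, list[PotencyAnnotation]] = defaultdict(list)
    for (canon, target_id, mtype), values in sorted(groups.items()):
        gm = aggregate_potency(values, criteria.max_value_ratio)
        if gm is None:
            reasons["inconsistent_values"] += 1
            continue
        rep_id = min(by_structure[canon]["ids"])
        annotations_by_structure[canon].append(
            PotencyAnnotation(rep_id, target_id, mtype, gm, len(values))
        )

    compounds: list[AnnotatedCompound] = []
    for canon in sorted(by_structure):
        anns = annotations_by_structure.get(canon)
        if not anns:
            reasons["no_surviving_annotation"] += 1
            continue
        rep_id = min(by_structure[canon]["ids"])
        comp = Compound(rep_id, canon, chem_core.count_heavy_atoms(canon))
        compounds.append(AnnotatedCompound(comp, sorted(anns, key=lambda a: (a.target_id, a.measurement_type))))
    compounds.sort(key=lambda ac: ac.compound.compound_id)
    return compounds, reasons
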