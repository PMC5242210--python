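"""End-to-end orchestration: curate -> fragment -> MMP -> series -> scaffold -> stats."""

from __future__ import annotations

import hashlib
import json
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from asbscaffolds.annotation_stats import PipelineStats, ScaffoldAnnotation, annotate_series, compute_stats
from asbscaffolds.asb_scaffold import (
    ASBScaffold,
    CoreCover,
    SKAssignment,
    compute_core_cover,
    find_sk_compounds,
    qualifying_cores,
    select_asb_scaffold,
)
from asbscaffolds.chem_core import RuleSet, load_default_rules
from asbscaffolds.curation import ActivityRecord, AnnotatedCompound, CurationConfig, build_compound_set
from asbscaffolds.mmp_engine import MMP, MMPConstraints, generate_mmps
from asbscaffolds.series_network import AnalogSeries, build_network, extract_series

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """All stage outputs of one pipeline run."""

    compounds: list[AnnotatedCompound]
    curation_report: Counter
    mmps: list[MMP]
    series: list[AnalogSeries]
    sk_assignments: list[SKAssignment]
    scaffolds: dict[str, ASBScaffold | None]
    covers: dict[str, CoreCover | None]
    annotations: dict[str, ScaffoldAnnotation]
    stats: PipelineStats
    n_qualifying: dict[str, int] = field(default_factory=dict)

    @property
    def compounds_by_id(self) -> dict[str, AnnotatedCompound]:
        return {ac.compound.compound_id: ac for ac in self.compounds}

    def stage_counts(self) -> dict[str, int]:
        return {
            "curated_compounds": len(self.compounds),
            "mmps": len(self.mmps),
            "series": len(self.series),
            "series_with_sk": sum(1 for a in self.sk_assignments if a.sk_compounds),
            "series_with_asb_scaffold": sum(1 for s in self.scaffolds.values() if s is not None),
            "series_with_core_cover": sum(1 for c in self.covers.values() if c is not None),
            "single_target_scaffolds": sum(
                1
                for sid, sc in self.scaffolds.items()
                if sc is not None and self.annotations[sid].multiplicity_class == "single"
            ),
            "multi_target_scaffolds": sum(
                1
                for sid, sc in self.scaffolds.items()
                if sc is not None and self.annotations[sid].multiplicity_class == "multi"
            ),
        }

    # ---- tabular exports ----------------------------------------------

    def mmp_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(
                    compound_a=m.compound_a,
                    compound_b=m.compound_b,
                    core_smiles=m.core.structure,
                    sub_a_smiles=m.substituent_a.structure,
                    sub_b_smiles=m.substituent_b.structure,
                    rule_id=m.rule_id,
                )
                for m in self.mmps
            ],
            columns=["compound_a", "compound_b", "core_smiles", "sub_a_smiles", "sub_b_smiles", "rule_id"],
        )

    def series_table(self) -> pd.DataFrame:
        rows = [
            dict(compound_id=m, series_id=s.series_id)
            for s in self.series
            for m in sorted(s.members)
        ]
        return pd.DataFrame(rows, columns=["compound_id", "series_id"])

    def scaffold_table(self) -> pd.DataFrame:
        rows = []
        for s in self.series:
            sc = self.scaffolds.get(s.series_id)
            if sc is None:
                continue
            ann = self.annotations[s.series_id]
            rows.append(
                dict(
                    series_id=s.series_id,
                    scaffold_smiles=sc.core.structure,
                    heavy_atoms=sc.heavy_atoms,
                    source_sk=sc.source_sk,
                    n_qualifying_cores=self.n_qualifying.get(s.series_id, 0),
                    n_series_members=s.size,
                    targets=";".join(sorted(ann.targets)),
                    multiplicity_class=ann.multiplicity_class,
                )
            )
        return pd.DataFrame(
            rows,
            columns=["series_id", "scaffold_smiles", "heavy_atoms", "source_sk", "n_qualifying_cores", "n_series_members", "targets", "multiplicity_class"],
        )

    def cover_table(self) -> pd.DataFrame:
        rows = []
        for s in self.series:
            cover = self.covers.get(s.series_id)
            if cover is None:
                continue
            rows.append(
                dict(
                    series_id=s.series_id,
                    cover_size=cover.size,
                    core_smiles_list=";".join(c.structure for c in cover.cores),
                    method=cover.method,
                )
            )
        return pd.DataFrame(rows, columns=["series_id", "cover_size", "core_smiles_list", "method"])

    def manifest(self) -> dict:
        payload = {
            "stage_counts": self.stage_counts(),
            "curation_report": dict(sorted(self.curation_report.items())),
        }
        digest = hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()
        return {**payload, "content_sha256": digest}


def run_pipeline(
    records: list[ActivityRecord],
    rules: RuleSet | None = None,
    constraints: MMPConstraints | None = None,
    curation: CurationConfig | None = None,
) -> PipelineResult:
    """Run every stage on raw activity records."""
    rules = rules or load_default_rules()
    constraints = constraints or MMPConstraints()
    compounds, report = build_compound_set(records, curation)
    mmps = generate_mmps([ac.compound for ac in compounds], rules, constraints)
    network = build_network(mmps)
    series = extract_series(network)
    by_id = {ac.compound.compound_id: ac for ac in compounds}

    sk_assignments: list[SKAssignment] = []
    scaffolds: dict[str, ASBScaffold | None] = {}
    covers: dict[str, CoreCover | None] = {}
    annotations: dict[str, ScaffoldAnnotation] = {}
    n_qualifying: dict[str, int] = {}
    for s in series:
        sk = find_sk_compounds(s)
        sk_assignments.append(sk)
        candidates = qualifying_cores(s, sk)
        n_qualifying[s.series_id] = len(candidates)
        scaffold = select_asb_scaffold(candidates, s)
        scaffolds[s.series_id] = scaffold
        covers[s.series_id] = (
            compute_core_cover(s, sk) if scaffold is None and sk.sk_compounds else None
        )
        annotations[s.series_id] = annotate_series(s, by_id, scaffold)

    stats = compute_stats(series, sk_assignments, scaffolds, annotations)
    return PipelineResult(
        compounds=compounds,
        curation_report=report,
        mmps=mmps,
        series=series,
        sk_assignments=sk_assignments,
        scaffolds=scaffolds,
        covers=covers,
        annotations=annotations,
        stats=stats,
        n_qualifying=n_qualifying,
    )
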