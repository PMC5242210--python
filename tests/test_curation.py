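"""Activity-record filtering, geometric-mean aggregation, compound dedup."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asbscaffolds.curation import (
    ActivityRecord,
    CurationConfig,
    aggregate_potency,
    build_compound_set,
    filter_records,
)


def record(**kw):
    base = dict(
        compound_id="c1",
        smiles="CCO",
        target_id="T1",
        target_organism="Homo sapiens",
        relationship_type="D",
        confidence_score=9,
        measurement_type="Ki",
        relation="=",
        value=100.0,
        unit="nM",
    )
    base.update(kw)
    return ActivityRecord(**base)


class TestFilterRecords:
    @pytest.mark.parametrize(
        "change,reason",
        [
            (dict(relation=">"), "approximate_relation"),
            (dict(relation="<"), "approximate_relation"),
            (dict(relation="~"), "approximate_relation"),
            (dict(confidence_score=8), "confidence_score"),
            (dict(relationship_type="H"), "relationship_type"),
            (dict(target_organism="Rattus norvegicus"), "organism"),
            (dict(measurement_type="EC50"), "measurement_type"),
            (dict(unit="mg/mL"), "unknown_unit"),
            (dict(value=0.0), "nonpositive_value"),
        ],
    )
    def test_each_criterion_discards(self, change, reason):
        kept, reasons = filter_records([record(**change)])
        assert kept == [] and reasons[reason] == 1

    def test_empty_input(self):
        kept, reasons = filter_records([])
        assert kept == [] and sum(reasons.values()) == 0

    @pytest.mark.parametrize("unit,factor", [("nM", 1.0), ("uM", 1e3), ("mM", 1e6), ("M", 1e9), ("pM", 1e-3)])
    def test_unit_conversion_to_nM(self, unit, factor):
        kept, _ = filter_records([record(value=2.5, unit=unit)])
        assert kept[0].value == pytest.approx(2.5 * factor) and kept[0].unit == "nM"

    def test_tightening_a_criterion_never_retains_more(self):
        records = [record(), record(confidence_score=8), record(measurement_type="IC50")]
        loose = CurationConfig()
        tight = CurationConfig(measurement_types=("Ki",))
        kept_loose, _ = filter_records(records, loose)
        kept_tight, _ = filter_records(records, tight)
        assert len(kept_tight) <= len(kept_loose)


class TestAggregatePotency:
    def test_singleton_is_identity(self):
        assert aggregate_potency([100.0]) == pytest.approx(100.0)

    def test_geometric_mean_by_hand(self):
        # oracle: exp(mean(log([5, 8]))) = sqrt(40)
        assert aggregate_potency([5.0, 8.0]) == pytest.approx(6.3246, abs=1e-4)
        assert aggregate_potency([5.0, 8.0]) == pytest.approx(math.sqrt(40.0))

    def test_values_spanning_more_than_one_order_discarded(self):
        assert aggregate_potency([100.0, 2000.0]) is None  # ratio 20 > 10
        assert aggregate_potency([100.0, 1000.0]) is not None  # ratio exactly 10

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            aggregate_potency([1.0, -2.0])
        with pytest.raises(ValueError):
            aggregate_potency([])

    @given(
        values=st.lists(st.floats(min_value=0.5, max_value=4.9), min_size=1, max_size=6),
        c=st.floats(min_value=0.01, max_value=100.0),
    )
    @settings(deadline=None, max_examples=50)
    def test_scale_equivariance(self, values, c):
        base = aggregate_potency(values)
        scaled = aggregate_potency([c * v for v in values])
        assert base is not None and scaled == pytest.approx(c * base, rel=1e-9)


class TestBuildCompoundSet:
    def test_dedup_by_canonical_structure_merges_targets(self):
        recs = [record(smiles="CCO", target_id="T1"), record(compound_id="c2", smiles="OCC", target_id="T2")]
        compounds, _ = build_compound_set(recs)
        assert len(compounds) == 1
        assert compounds[0].target_ids == {"T1", "T2"}

    def test_compound_with_only_approximate_record_absent(self):
        compounds, _ = build_compound_set([record(relation="~")])
        assert compounds == []

    def test_three_singletons(self):
        recs = [
            record(compound_id="a", smiles="CCO"),
            record(compound_id="b", smiles="CCN"),
            record(compound_id="c", smiles="CCC(=O)O"),
        ]
        compounds, _ = build_compound_set(recs)
        assert len(compounds) == 3
        assert all(len(ac.annotations) == 1 for ac in compounds)

    def test_ki_and_ic50_never_averaged_together(self):
        recs = [record(value=10.0), record(measurement_type="IC50", value=100000.0)]
        compounds, _ = build_compound_set(recs)
        anns = {(a.measurement_type, a.potency_nM) for a in compounds[0].annotations}
        assert anns == {("Ki", 10.0), ("IC50", 100000.0)}

    def test_inconsistent_values_drop_the_pair(self):
        recs = [record(value=1.0), record(value=100.0)]
        compounds, reasons = build_compound_set(recs)
        assert compounds == [] and reasons["inconsistent_values"] == 1

    def test_unparsable_structure_dropped_with_diagnostic(self):
        compounds, reasons = build_compound_set([record(smiles="xx((")])
        assert compounds == [] and reasons["structure_parse_failure"] == 1

    def test_salt_forms_merge_with_parent(self):
        recs = [record(smiles="CCNC(=O)c1ccccc1"), record(compound_id="c2", smiles="CCNC(=O)c1ccccc1.Cl", target_id="T2")]
        compounds, _ = build_compound_set(recs)
        assert len(compounds) == 1 and compounds[0].target_ids == {"T1", "T2"}

    def test_dedup_idempotent(self):
        recs = [record(), record(compound_id="c2", smiles="OCC", target_id="T2")]
        once, _ = build_compound_set(recs)
        again, _ = build_compound_set(
            [
                record(compound_id=ac.compound.compound_id, smiles=ac.compound.structure, target_id=a.target_id,
                       measurement_type=a.measurement_type, value=a.potency_nM)
                for ac in once
                for a in ac.annotations
            ]
        )
        assert [(ac.compound.structure, ac.target_ids) for ac in again] == [
            (ac.compound.structure, ac.target_ids) for ac in once
        ]
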