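"""Target-activity annotation of series/scaffolds and pipeline statistics.

Every analog series is built from curated active compounds, so each series
(and hence each scaffold) inherits the union of its members' target
annotations.  The statistics table has three columns — all series, series
with SK compounds, series with an ASB scaffold — with counts of series
(split into single- and multi-target), compounds, SK compounds, targets,
and series-size summaries; percentages are relative to the all-series
column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from asbscaffolds.asb_scaffold import ASBScaffold, SKAssignment
from asbscaffolds.curation import AnnotatedCompound
from asbscaffolds.series_network import AnalogSeries

__all__ = ["PipelineStats", "ScaffoldAnnotation", "StageStats", "annotate_scaffold", "annotate_series", "compute_stats"]


@dataclass(frozen=True)
class ScaffoldAnnotation:
    """Targets of a series/scaffold: union over member compounds."""

    series_id: str
    scaffold: ASBScaffold | None
    targets: frozenset[str]
    multiplicity_class: str  # "single" | "multi"
    #: per measurement type (Ki / IC50), the targets annotated through it
    targets_by_type: dict[str, frozenset[str]] = field(default_factory=dict, compare=False)


@dataclass
class StageStats:
    """One column of the statistics table."""

    n_series: int = 0
    n_single_target: int = 0
    n_multi_target: int = 0
    n_compounds: int = 0
    n_sk_compounds: int | None = None
    size_min: int = 0
    size_max: int = 0
    size_mean: float = 0.0
    n_targets: int = 0


@dataclass
class PipelineStats:
    all_series: StageStats
    with_sk: StageStats
    with_asb: StageStats

    def as_table(self) -> list[list[str]]:
        """Three-column rows; percentages against the all-series column."""
        base = self.all_series

        def pct(n: int, d: int) -> str:
            return f"{n:,} ({round(100 * n / d)}%)" if d else "–"

        def col(st: StageStats, with_pct: bool) -> list[str]:
            if st.n_series == 0:
                return ["–"] * 7
            series = pct(st.n_series, base.n_series) if with_pct else f"{st.n_series:,}"
            cpds = pct(st.n_compounds, base.n_compounds) if with_pct else f"{st.n_compounds:,}"
            sk = "–" if st.n_sk_compounds is None else pct(st.n_sk_compounds, base.n_compounds)
            return [
                series,
                f"{st.n_single_target:,}",
                f"{st.n_multi_target:,}",
                cpds,
                sk,
                f"{st.size_min}–{st.size_max}" if st.n_series else "–",
                f"{st.size_mean:.1f}",
            ]

        rows = [
            ["Analog series (n)"],
            ["Single target"],
            ["Multiple targets"],
            ["CPDs (n)"],
            ["SK CPDs (n)"],
            ["Analog series size"],
            ["Mean"],
            ["Targets (n)"],
        ]
        cols = [
            col(self.all_series, False) + [f"{self.all_series.n_targets:,}"],
            col(self.with_sk, True) + [f"{self.with_sk.n_targets:,}"],
            col(self.with_asb, True) + [f"{self.with_asb.n_targets:,}"],
        ]
        for row, *vals in zip(rows, *cols):
            row.extend(vals)
        return rows


def annotate_series(
    series: AnalogSeries,
    compounds_by_id: dict[str, AnnotatedCompound],
    scaffold: ASBScaffold | None = None,
) -> ScaffoldAnnotation:
    """Union of member target annotations, with a per-type breakdown."""
    targets: set[str] = set()
    by_type: dict[str, set[str]] = {}
    for member in series.members:
        try:
            ac = compounds_by_id[member]
        except KeyError:
            raise ValueError(
                f"series {series.series_id}: member {member!r} lacks activity annotations"
            ) from None
        for ann in ac.annotations:
            targets.add(ann.target_id)
            by_type.setdefault(ann.measurement_type, set()).add(ann.target_id)
    if not targets:
        raise ValueError(f"series {series.series_id}: no targets among members")
    return ScaffoldAnnotation(
        series_id=series.series_id,
        scaffold=scaffold,
        targets=frozenset(targets),
        multiplicity_class="single" if len(targets) == 1 else "multi",
        targets_by_type={t: frozenset(v) for t, v in sorted(by_type.items())},
    )


def annotate_scaffold(
    series: AnalogSeries,
    scaffold: ASBScaffold,
    compounds_by_id: dict[str, AnnotatedCompound],
) -> ScaffoldAnnotation:
    """Annotation of a series that yielded an ASB scaffold."""
    return annotate_series(series, compounds_by_id, scaffold)


def _stage(
    series_list: list[AnalogSeries],
    annotations: dict[str, ScaffoldAnnotation],
    sk_by_series: dict[str, SKAssignment],
    count_sk: bool,
) -> StageStats:
    st = StageStats()
    st.n_series = len(series_list)
    if not series_list:
        return st
    sizes = [s.size for s in series_list]
    members: set[str] = set()
    sk_members: set[str] = set()
    targets: set[str] = set()
    for s in series_list:
        members |= s.members
        ann = annotations[s.series_id]
        targets |= ann.targets
        if ann.multiplicity_class == "single":
            st.n_single_target += 1
        else:
            st.n_multi_target += 1
        if count_sk:
            sk_members |= sk_by_series[s.series_id].sk_compounds
    st.n_compounds = len(members)
    st.n_sk_compounds = len(sk_members) if count_sk else None
    st.size_min, st.size_max = min(sizes), max(sizes)
    st.size_mean = sum(sizes) / len(sizes)
    st.n_targets = len(targets)
    return st


def compute_stats(
    all_series: list[AnalogSeries],
    sk_assignments: list[SKAssignment],
    scaffolds: dict[str, ASBScaffold | None],
    annotations: dict[str, ScaffoldAnnotation],
) -> PipelineStats:
    """Three-stage statistics: all series / with SK compounds / with scaffold."""
    sk_by_series = {a.series_id: a for a in sk_assignments}
    with_sk = [s for s in all_series if sk_by_series[s.series_id].sk_compounds]
    with_asb = [s for s in with_sk if scaffolds.get(s.series_id) is not None]
    return PipelineStats(
        all_series=_stage(all_series, annotations, sk_by_series, False),
        with_sk=_stage(with_sk, annotations, sk_by_series, True),
        with_asb=_stage(with_asb, annotations, sk_by_series, True),
    )
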