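"""Ground-truth fixture generation: designed analog series plus decoys.

Each designed series is one core template (a fragment with a single
attachment point at a RECAP-cleavable bond) enumerated with distinct
R-groups, so the expected analog series, structural-key compounds, ASB
scaffold and core-cover outcomes are known by construction.  The default
specification exercises the constraint boundaries — substituent sizes 12,
13 and 14 heavy atoms around the 13-atom cap, and core/substituent ratios
at and below the 2.0 threshold — as well as two-site variation series that
must yield a core cover instead of a scaffold, and series designed to
produce no MMPs at all.  Decoys are rigid (poly)cyclic structures without
any cleavable acyclic bond, so they survive curation but stay isolated.

Activity records are synthetic: every compound receives exact Ki or IC50
values against designated protein targets, drawn log-uniformly from
1–10,000 nM.  The values are irrelevant to the scaffold logic but satisfy
all curation filters; a configurable sprinkle of approximate/low-confidence
records exercises the filters without changing the designed outcomes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from asbscaffolds import chem_core
from asbscaffolds.chem_core import canonicalize_fragment, load_default_rules, reassemble
from asbscaffolds.mmp_engine import MMPConstraints

__all__ = ["FixtureSpec", "FixtureTruth", "SeriesTruth", "TargetModel", "generate_decoys", "generate_fixture", "generate_series"]

# Core templates for plain designed series: (rule_id, fragment SMILES).
# None contains a cleavable bond internally, and all canonical strings are
# pairwise distinct, so no two series can share a core.
STANDARD_TEMPLATES: list[tuple[str, str]] = [
    ("amide", "[*]C(=O)c1ccc2ccccc2c1"),
    ("amide", "[*]C(=O)c1ccc2cc(F)ccc2c1"),
    ("amide", "[*]C(=O)c1ccc2cc(Cl)ccc2c1"),
    ("amide", "[*]C(=O)c1ccc2cc(C)ccc2c1"),
    ("ester", "[*]C(=O)c1cccc2ccccc12"),
    ("ester", "[*]C(=O)c1cccc2cc(F)ccc12"),
    ("ester", "[*]C(=O)c1cccc2cc(Cl)ccc12"),
    ("ester", "[*]C(=O)c1cccc2cc(Br)ccc12"),
    ("ether", "[*]Oc1ccc2ccccc2c1"),
    ("ether", "[*]Oc1ccc2cc(F)ccc2c1"),
    ("ether", "[*]Oc1ccc2cc(Cl)ccc2c1"),
    ("ether", "[*]Oc1ccc2cc(C)ccc2c1"),
]

# Small-substituent pools keyed by the attachment-root element the rule
# needs (amide: N-rooted, ester: O-rooted, ether: C-rooted).  Alkyl /
# fluoroalkyl / cycloalkyl only: none introduces a cleavable bond.
RGROUP_POOLS: dict[str, list[str]] = {
    "amide": [
        "[*]N", "[*]NC", "[*]NCC", "[*]NCCC", "[*]NC(C)C", "[*]NCCF",
        "[*]NCCCC", "[*]NC(C)CC", "[*]NCC(C)C", "[*]NCCCF", "[*]NC1CCC1",
        "[*]NCCCCC", "[*]NC1CCCC1", "[*]NC(C)CCC", "[*]NCC(C)CC", "[*]NCCCCF",
    ],
    "ester": [
        "[*]OC", "[*]OCC", "[*]OCCC", "[*]OC(C)C", "[*]OCCF",
        "[*]OCCCC", "[*]OC(C)CC", "[*]OCC(C)C", "[*]OCCCF", "[*]OC1CCC1",
        "[*]OCCCCC", "[*]OC1CCCC1", "[*]OC(C)CCC", "[*]OCCCCF", "[*]OCC(C)CC",
    ],
    "ether": [
        "[*]C", "[*]CC", "[*]CCC", "[*]C(C)C", "[*]CCF",
        "[*]CCCC", "[*]CC(C)C", "[*]C(C)CC", "[*]CCCF", "[*]C1CCC1",
        "[*]CCCCC", "[*]C1CCCC1", "[*]CCC(C)C", "[*]CCCCF", "[*]CC(C)CC",
    ],
}

# 29-heavy-atom amide cores paired with 12/13/14-atom substituents probe the
# 13-atom substituent cap (29 >= 2*13 but the 14-atom R-group is too big);
# the 20-heavy variant is too small for any of them (20 < 24), a series
# designed to produce no MMPs.
BOUNDARY_TEMPLATES: list[str] = [
    "[*]C(=O)c1ccc(CCCCCCCCCCc2ccc3ccccc3c2)cc1F",
    "[*]C(=O)c1ccc(CCCCCCCCCCc2ccc3ccccc3c2)cc1Cl",
    "[*]C(=O)c1ccc(CCCCCCCCCCc2ccc3ccccc3c2)cc1Br",
    "[*]C(=O)c1ccc(CCCCCCCCCCc2ccc3ccccc3c2)cc1C",
]
BOUNDARY_FAIL_TEMPLATE = "[*]C(=O)c1ccc(CCc2ccc3ccccc3c2)cc1"
BOUNDARY_RGROUPS = ["[*]NCc1ccc2ccccc2c1", "[*]NCCc1ccc2ccccc2c1", "[*]NCCCc1ccc2ccccc2c1"]

# 8-heavy azaaroyl cores with 2/3/4/5-atom substituents probe the 2:1
# core/substituent ratio (8 >= 2*4 holds exactly; 8 < 2*5 fails).
RATIO_TEMPLATES: list[str] = [
    "[*]C(=O)c1ccccn1",
    "[*]C(=O)c1cccnc1",
    "[*]C(=O)c1ccncc1",
    "[*]C(=O)c1ccncn1",
    "[*]C(=O)c1cnccn1",
]
RATIO_RGROUPS = ["[*]NC", "[*]NCC", "[*]NCCC", "[*]NCCCC"]

# Two-site variation family (ring decoration X makes the variants distinct):
# member A carries both reference substituents, B varies the amide side,
# C varies the ether side.  A is the sole SK compound and no single core
# covers the series; the designed outcome is a core cover of size 2.
TWO_SITE_DECORATIONS = ["", "F", "Cl", "Br", "I", "C"]

# Decoy bases: fused ring systems (all bonds in rings) decorated at one
# aromatic position; no acyclic bond matches any retrosynthetic rule.
DECOY_BASES: list[str] = [
    "{x}c1ccc2ccccc2c1",          # naphthalene
    "{x}c1ccc2ncccc2c1",          # quinoline
    "{x}c1ccc2cnccc2c1",          # isoquinoline
    "{x}c1ccc2[nH]ccc2c1",        # indole
    "{x}c1ccc2c(c1)Cc1ccccc12",   # fluorene
    "{x}c1ccc2cc3ccccc3cc2c1",    # anthracene
    "{x}c1ccc2c(c1)ccc1ccccc12",  # phenanthrene
    "{x}c1ccc2c(c1)oc1ccccc12",   # dibenzofuran
    "{x}c1ccc2c(c1)sc1ccccc12",   # dibenzothiophene
    "{x}c1ccc2c(c1)[nH]c1ccccc12",  # carbazole
]
DECOY_DECORATIONS = ["", "F", "Cl", "Br", "I", "C"]


@dataclass
class TargetModel:
    n_targets: int = 8
    multi_target_fraction: float = 0.3


@dataclass
class FixtureSpec:
    """Recipe for a seeded ground-truth compound set."""

    n_series: int = 25
    members_min: int = 2
    members_max: int = 10
    scaffold_pool: list[tuple[str, str]] = field(default_factory=lambda: list(STANDARD_TEMPLATES))
    rgroup_pool: dict[str, list[str]] = field(default_factory=lambda: {k: list(v) for k, v in RGROUP_POOLS.items()})
    n_decoys: int = 50
    seed: int = 0
    target_model: TargetModel = field(default_factory=TargetModel)
    include_two_site: bool = True
    include_boundary: bool = True
    constraints: MMPConstraints = field(default_factory=MMPConstraints)
    filtered_record_rate: float = 0.15
    n_censored_compounds: int = 2


@dataclass
class SeriesTruth:
    """Designed outcome of one generated series."""

    label: str
    kind: str  # standard | two_site | boundary | ratio | no_mmp
    designed_core: str  # canonical fragment SMILES
    all_member_ids: tuple[str, ...]
    expected_members: frozenset[str]  # expected analog-series membership
    expected_excluded: frozenset[str]  # designed isolated (constraint-violating)
    expected_sk: frozenset[str]
    expected_scaffold: str | None  # canonical fragment SMILES, None if cover/no series
    expected_cover_size: int | None
    targets: frozenset[str]


@dataclass
class FixtureTruth:
    """Self-consistent designed outcomes for a whole fixture."""

    series: list[SeriesTruth]
    decoy_ids: tuple[str, ...]
    dropped_ids: tuple[str, ...]  # compounds whose records never pass curation

    @property
    def expected_series_memberships(self) -> set[frozenset[str]]:
        return {t.expected_members for t in self.series if len(t.expected_members) >= 2}

    def to_dict(self) -> dict:
        return {
            "series": [
                {
                    "label": t.label,
                    "kind": t.kind,
                    "designed_core": t.designed_core,
                    "all_member_ids": list(t.all_member_ids),
                    "expected_members": sorted(t.expected_members),
                    "expected_excluded": sorted(t.expected_excluded),
                    "expected_sk": sorted(t.expected_sk),
                    "expected_scaffold": t.expected_scaffold,
                    "expected_cover_size": t.expected_cover_size,
                    "targets": sorted(t.targets),
                }
                for t in self.series
            ],
            "decoy_ids": list(self.decoy_ids),
            "dropped_ids": list(self.dropped_ids),
        }


class _Emitter:
    """Accumulates compounds + activity records with uniqueness checks."""

    COLUMNS = [
        "compound_id", "smiles", "target_id", "organism", "relationship_type",
        "confidence_score", "standard_type", "standard_relation",
        "standard_value", "standard_units",
    ]

    def __init__(self, spec: FixtureSpec, rng: np.random.Generator):
        self.spec = spec
        self.rng = rng
        self.rows: list[dict] = []
        self.structures: dict[str, str] = {}  # canonical smiles -> compound_id
        self._n = 0
        self.rules = load_default_rules()

    def new_compound(self, smiles: str) -> str | None:
        canon = chem_core.canonicalize(smiles)
        if canon in self.structures:
            return None  # duplicate structure: caller rejects at generation
        self._n += 1
        cid = f"CPD{self._n:05d}"
        self.structures[canon] = cid
        return cid

    def potency_rows(self, cid: str, smiles: str, target: str, censored: bool = False) -> None:
        rng, spec = self.rng, self.spec
        mtype = "Ki" if rng.random() < 0.5 else "IC50"
        base = float(10 ** rng.uniform(0, 4))  # 1 .. 10^4 nM
        values = [base]
        if rng.random() < 0.3:  # replicate within one order of magnitude
            values.append(base * float(rng.uniform(1.0, 3.0)))
        for v in values:
            if rng.random() < 0.2:  # exercise unit conversion
                value, unit = v / 1e3, "uM"
            else:
                value, unit = v, "nM"
            self.rows.append(
                dict(
                    compound_id=cid, smiles=smiles, target_id=target,
                    organism="Homo sapiens", relationship_type="D",
                    confidence_score=9, standard_type=mtype,
                    standard_relation=">" if censored else "=",
                    standard_value=value, standard_units=unit,
                )
            )
        if not censored and rng.random() < spec.filtered_record_rate:
            # a record the curation filters must reject, harmless to truth
            bad = rng.integers(0, 3)
            row = dict(
                compound_id=cid, smiles=smiles, target_id=target,
                organism="Homo sapiens", relationship_type="D",
                confidence_score=9, standard_type=mtype,
                standard_relation="=", standard_value=base, standard_units="nM",
            )
            if bad == 0:
                row["standard_relation"] = ">"
            elif bad == 1:
                row["confidence_score"] = 8
            else:
                row["organism"] = "Rattus norvegicus"
            self.rows.append(row)

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows, columns=self.COLUMNS)
        return df.sort_values(["compound_id", "target_id", "standard_type", "standard_value"], kind="mergesort").reset_index(drop=True)


def _expected_in_series(core_heavy: int, sub_heavy: int, c: MMPConstraints) -> bool:
    """Constraint arithmetic defining designed membership for one-site series."""
    return sub_heavy <= c.max_substituent_heavy_atoms and core_heavy >= c.core_to_substituent_ratio * sub_heavy


def _series_targets(emitter: _Emitter, label: str) -> tuple[str, str | None]:
    tm = emitter.spec.target_model
    primary = f"T{emitter.rng.integers(1, tm.n_targets + 1):04d}"
    secondary = None
    if emitter.rng.random() < tm.multi_target_fraction:
        k = int(emitter.rng.integers(1, tm.n_targets + 1))
        secondary = f"T{k:04d}"
        if secondary == primary:
            secondary = f"T{(k % tm.n_targets) + 1:04d}"
    return primary, secondary


def _one_site_series(
    emitter: _Emitter, label: str, kind: str, template: str, rgroups: list[str]
) -> SeriesTruth:
    """One template + enumerated R-groups; membership by constraint arithmetic."""
    spec = emitter.spec
    core = canonicalize_fragment(template)
    primary, secondary = _series_targets(emitter, label)
    member_ids: list[str] = []
    in_series: list[str] = []
    excluded: list[str] = []
    for rg in rgroups:
        sub = canonicalize_fragment(rg)
        smiles = reassemble(core, sub)
        cuts = emitter.rules.matching_bonds(chem_core._parse(smiles))
        if len(cuts) != 1:
            raise ValueError(
                f"fixture specification error: {smiles} has {len(cuts)} cleavable bonds, expected 1"
            )
        cid = emitter.new_compound(smiles)
        if cid is None:
            raise ValueError(f"fixture specification error: duplicate member {smiles}")
        member_ids.append(cid)
        target = primary
        if secondary is not None and emitter.rng.random() < 0.5:
            emitter.potency_rows(cid, smiles, secondary)
        emitter.potency_rows(cid, smiles, target)
        if _expected_in_series(core.heavy_atoms, sub.heavy_atoms, spec.constraints):
            in_series.append(cid)
        else:
            excluded.append(cid)
    forms_series = len(in_series) >= 2
    return SeriesTruth(
        label=label,
        kind=kind if forms_series else "no_mmp",
        designed_core=core.structure,
        all_member_ids=tuple(member_ids),
        expected_members=frozenset(in_series) if forms_series else frozenset(),
        expected_excluded=frozenset(excluded) | (frozenset(in_series) if not forms_series else frozenset()),
        expected_sk=frozenset(in_series) if forms_series else frozenset(),
        expected_scaffold=core.structure if forms_series else None,
        expected_cover_size=None,
        targets=frozenset(),
    )


def _two_site_series_build(emitter: _Emitter, label: str, decoration: str) -> SeriesTruth:
    """A / B / C analogs varied at two sites: SK = {A}, cover of size 2."""
    # member SMILES: methoxy / N-methyl reference, then one site varied at a time
    if decoration:
        a = f"COc1cc({decoration})ccc1C(=O)NC"
        b = f"COc1cc({decoration})ccc1C(=O)NCC"
        c = f"CCOc1cc({decoration})ccc1C(=O)NC"
    else:
        a = "COc1ccccc1C(=O)NC"
        b = "COc1ccccc1C(=O)NCC"
        c = "CCOc1ccccc1C(=O)NC"
    primary, secondary = _series_targets(emitter, label)
    ids = []
    for smiles in (a, b, c):
        cuts = emitter.rules.matching_bonds(chem_core._parse(chem_core.canonicalize(smiles)))
        if len(cuts) != 2:
            raise ValueError(f"fixture specification error: {smiles} has {len(cuts)} cleavable bonds, expected 2")
        cid = emitter.new_compound(smiles)
        if cid is None:
            raise ValueError(f"fixture specification error: duplicate two-site member {smiles}")
        ids.append(cid)
        if secondary is not None and emitter.rng.random() < 0.5:
            emitter.potency_rows(cid, smiles, secondary)
        emitter.potency_rows(cid, smiles, primary)
    return SeriesTruth(
        label=label,
        kind="two_site",
        designed_core="",
        all_member_ids=tuple(ids),
        expected_members=frozenset(ids),
        expected_excluded=frozenset(),
        expected_sk=frozenset({ids[0]}),
        expected_scaffold=None,
        expected_cover_size=2,
        targets=frozenset(),
    )


def generate_series(spec: FixtureSpec, emitter: _Emitter | None = None) -> tuple[pd.DataFrame, FixtureTruth]:
    """Designed series per the fixture specification; returns (activity table, truth).

    Series roles cycle: plain one-template series from the scaffold pool,
    two-site cover series, substituent-cap boundary series (12/13/14 heavy
    atoms, one designed to yield no MMPs at all), and core/substituent
    ratio boundary series.
    """
    own = emitter is None
    if own:
        emitter = _Emitter(spec, np.random.default_rng(spec.seed))
    rng = emitter.rng
    truths: list[SeriesTruth] = []
    std_templates = itertools.cycle(spec.scaffold_pool)
    two_site_dec = itertools.cycle(TWO_SITE_DECORATIONS)
    boundary_templates = itertools.cycle(BOUNDARY_TEMPLATES)
    ratio_templates = itertools.cycle(RATIO_TEMPLATES)
    n_boundary_seen = 0
    for i in range(spec.n_series):
        label = f"series{i:03d}"
        role = i % 5
        if role == 2 and spec.include_two_site:
            truths.append(_two_site_series_build(emitter, label, next(two_site_dec)))
        elif role == 3 and spec.include_boundary:
            n_boundary_seen += 1
            if n_boundary_seen % 5 == 0:  # every fifth: core too small for any R-group
                template = BOUNDARY_FAIL_TEMPLATE
            else:
                template = next(boundary_templates)
            truths.append(_one_site_series(emitter, label, "boundary", template, list(BOUNDARY_RGROUPS)))
        elif role == 4 and spec.include_boundary:
            truths.append(_one_site_series(emitter, label, "ratio", next(ratio_templates), list(RATIO_RGROUPS)))
        else:
            rule_id, template = next(std_templates)
            core = canonicalize_fragment(template)
            max_sub = int(core.heavy_atoms // spec.constraints.core_to_substituent_ratio)
            pool = [
                rg
                for rg in spec.rgroup_pool[rule_id]
                if canonicalize_fragment(rg).heavy_atoms <= max_sub
            ]
            k = int(rng.integers(spec.members_min, spec.members_max + 1))
            k = min(k, len(pool))
            chosen = sorted(rng.choice(len(pool), size=k, replace=False))
            truths.append(
                _one_site_series(emitter, label, "standard", template, [pool[j] for j in chosen])
            )
    # annotate truth targets from the emitted rows
    by_id: dict[str, set[str]] = {}
    for row in emitter.rows:
        if row["standard_relation"] == "=" and row["confidence_score"] == 9 and row["organism"] == "Homo sapiens":
            by_id.setdefault(row["compound_id"], set()).add(row["target_id"])
    truths = [
        SeriesTruth(
            **{
                **t.__dict__,
                "targets": frozenset().union(*(by_id.get(m, set()) for m in t.expected_members), frozenset()),
            }
        )
        for t in truths
    ]
    truth = FixtureTruth(series=truths, decoy_ids=(), dropped_ids=())
    return emitter.frame(), truth


def generate_decoys(spec: FixtureSpec, emitter: _Emitter) -> list[str]:
    """Curation-passing compounds with no cleavable bonds: always isolated."""
    decoys: list[str] = []
    candidates = [base.format(x=dec) for base in DECOY_BASES for dec in DECOY_DECORATIONS]
    if spec.n_decoys > len(candidates):
        raise ValueError(f"at most {len(candidates)} distinct decoys available")
    for smiles in candidates:
        if len(decoys) == spec.n_decoys:
            break
        canon = chem_core.canonicalize(smiles)
        if emitter.rules.matching_bonds(chem_core._parse(canon)):
            raise ValueError(f"fixture specification error: decoy {smiles} has a cleavable bond")
        cid = emitter.new_compound(canon)
        if cid is None:
            continue  # collides with an existing structure: reject at generation
        target = f"T{emitter.rng.integers(1, spec.target_model.n_targets + 1):04d}"
        emitter.potency_rows(cid, canon, target)
        decoys.append(cid)
    if len(decoys) < spec.n_decoys:
        raise ValueError("not enough unique decoys after collision rejection")
    return decoys


# spare templates reserved for compounds whose only records are censored
CENSORED_TEMPLATES = [
    ("[*]C(=O)c1ccc2cc(I)ccc2c1", "[*]NC"),
    ("[*]Oc1ccc2cc(Br)ccc2c1", "[*]CC"),
    ("[*]C(=O)c1cccc2cc(I)ccc12", "[*]OCC"),
]


def generate_fixture(spec: FixtureSpec | None = None) -> tuple[pd.DataFrame, FixtureTruth]:
    """Full fixture: designed series + decoys + curation-dropped compounds."""
    spec = spec or FixtureSpec()
    emitter = _Emitter(spec, np.random.default_rng(spec.seed))
    _, truth = generate_series(spec, emitter)
    decoy_ids = generate_decoys(spec, emitter)
    dropped: list[str] = []
    for template, rg in CENSORED_TEMPLATES[: spec.n_censored_compounds]:
        smiles = reassemble(canonicalize_fragment(template), canonicalize_fragment(rg))
        cid = emitter.new_compound(smiles)
        if cid is None:
            raise ValueError("fixture specification error: censored compound duplicates another")
        target = f"T{emitter.rng.integers(1, spec.target_model.n_targets + 1):04d}"
        emitter.potency_rows(cid, smiles, target, censored=True)
        dropped.append(cid)
    truth = FixtureTruth(series=truth.series, decoy_ids=tuple(decoy_ids), dropped_ids=tuple(dropped))
    return emitter.frame(), truth
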