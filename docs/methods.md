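# Methods

## The procedure

The package implements a deterministic pipeline from a raw compound/activity
table to annotated analog series-based (ASB) scaffolds.

**Curation.**  Activity records are kept when they describe a direct
interaction (relationship type `D`) with a human target (`Homo sapiens`) at
the highest assay confidence (confidence score 9), report an exact value
(relation `=`; the approximate qualifiers `>`, `<`, `~` are discarded), use a
measurement type in {Ki, IC50}, and carry a concentration unit convertible to
nM (M, mM, µM, nM, pM).  Per compound, target and measurement type, repeated
values are merged into one potency annotation as their geometric mean,
provided max/min ≤ 10; wider-spread values are considered irreproducible and
the pair is dropped.  "Same order of magnitude" is operationalised as that
factor-10 dynamic range — the tightest natural reading — and is configurable
(`CurationConfig.max_value_ratio`).  Ki- and IC50-derived values are never
averaged together; a compound-target pair with either annotation counts as
active.  Structures are stripped to their largest covalent component
(salts/solvates logged), canonicalized as isomeric SMILES with RDKit, and
deduplicated by canonical string; stereoisomers therefore remain distinct
compounds.  Every rejection is counted per reason in the curation report.

**Fragmentation.**  Each compound is cut once at every distinct acyclic bond
matching one of eleven retrosynthetic (RECAP-type) bond patterns — amide,
ester, amine, urea, ether, olefin, quaternary N, aromatic N–aliphatic C,
lactam N–aliphatic C, aromatic C–aromatic C, sulfonamide — expressed as
SMARTS in `src/asbscaffolds/data/recap_rules.yaml`.  Only single cuts are
performed, because an MMP is defined by a modification at one and only one
site.  Each cut yields a core/substituent fragment pair in both orientations;
symmetry-equivalent cuts collapse under canonicalization.  The original rule
set is named in the literature without a precise dialect, so the dialect
choices here are explicit in the config and deliberately conservative:
amide/sulfonamide nitrogens are not treated as amine nitrogens (so
N-alkyl bonds of amides are not cut), the ester oxygen is not an ether
oxygen, and the biaryl rule cuts only bonds between two aromatic atoms.
Any of this can be overridden by supplying an alternative rule YAML.

**MMP generation.**  Two compounds form an MMP when they share an identical
canonical core fragment with different substituents, subject to the analog
size restrictions: the larger substituent ≤ 13 heavy atoms, and the core at
least 2.0× the larger substituent (both configurable via `MMPConstraints`).
The stated consequence — substituents at most a fused two-ring system plus
three atoms — is treated as exactly that, a consequence of the 13-atom cap,
not an additional topological filter.  Generation indexes all fragment pairs
by canonical core string and enumerates candidate pairs only within a
bucket; this is provably equivalent to all-pairs comparison and the package
carries an O(n²) brute-force generator (`generate_mmps_bruteforce`) used as
an independent oracle in the tests.  If one compound pair shares one core
through several substituent combinations (a rare symmetric case), a single
record per (pair, core) is kept, choosing the lexicographically smallest
substituent pair; both generators use the same convention.

**Series, SK compounds, scaffolds.**  The MMP network (networkx graph, one
edge per compound pair, annotated with all shared cores) is split into
connected components; each component of ≥ 2 compounds is an analog series,
ordered by smallest member identifier.  No additional pruning (e.g. removal
of promiscuous cores) is applied.  SK compounds are the members of
within-series degree |members|−1.  A core of an SK compound *qualifies* when
the MMP between that SK compound and every other member uses exactly that
core; qualifying cores are pooled across all SK compounds of a series
(collapsed by canonical string, attributed to the smallest owning SK
identifier).  The ASB scaffold is the qualifying core with the most heavy
atoms; equal-sized candidates are broken by lexicographic order of the
canonical string, purely for determinism.  For series with SK compounds but
no qualifying core, a minimum-cardinality core cover is computed: exact
enumeration over subsets when there are ≤ 20 candidate cores (default,
configurable), greedy set cover beyond that, with the method recorded in the
output.  A defensive branch returns no cover if the SK cores fail to span
the series — impossible by the SK definition, but checked.

**Annotation and statistics.**  Each series inherits the union of its
members' target annotations and is classed single- or multi-target.  The
statistics table reports, at three stages (all series / series with SK
compounds / series with an ASB scaffold), the number of series with the
single/multi split, compounds, SK compounds, targets, and series-size
min/max/mean; percentages are computed against the all-series column, and
a per-measurement-type target breakdown is written alongside the pooled
counts.

## Synthetic study conditions

The fixture generator produces compound sets with designed outcomes so the
whole pipeline is testable without any external download.  A designed series
is one core template — a fragment with a single attachment point at a bond
matching the amide, ester or ether rule (the rules least sensitive to
dialect choices) — reassembled with k distinct R-groups.  Templates are
pairwise distinct, contain no internal cleavable bond, and have ≥ 8 heavy
atoms while R-groups have ≤ 14, which provably prevents any cross-series
MMP; each assembled compound is verified at generation time to contain
exactly one cleavable bond (two for the two-site family).  Membership truth
is pure constraint arithmetic: a member with an R-group of s heavy atoms
joins its series iff s ≤ 13 and core ≥ 2s, and excluded members must end up
isolated.

The default specification (25 series, sizes 2–10, 50 decoys, seed-driven)
cycles five roles: plain series (expected scaffold = the designed core),
two-site variation series (an A/B/C triple varied at the ether and amide
sites of a salicylamide-like scaffold: SK = {A}, no single qualifying core,
expected cover size 2), substituent-cap boundary series (R-groups of 12, 13
and 14 heavy atoms on a 29-atom core: the 14-atom member must stay out;
every fifth such series uses a 20-atom core on which *no* R-group passes,
designing a series that yields no MMPs at all), and ratio boundary series
(8-atom azaaroyl cores with 2/3/4/5-atom R-groups: the 4-atom member sits
exactly at core = 2×substituent and is in, the 5-atom member is out).
Decoys are fused polycyclics (naphthalene, quinoline, indole, fluorene,
anthracene, dibenzofuran, carbazole, ... with halogen/methyl decorations)
verified at generation to contain no cleavable acyclic bond, so they pass
curation but stay isolated.  Potencies are log-uniform in 1–10⁴ nM —
irrelevant to the scaffold logic but satisfying every curation filter —
with occasional µM-unit records, duplicate measurements within one order of
magnitude, and a sprinkle of records designed to be rejected (approximate
relation, confidence 8, non-human organism) plus two compounds whose only
records are censored and must vanish at curation.

What the fixtures do *not* emulate: realistic SAR (potencies are independent
of structure), chemotype diversity beyond the template families, tautomer or
stereochemistry edge cases, and the heavy-tailed series-size distribution of
real repositories.  Passing the recovery tests therefore demonstrates the
correctness of the combinatorial machinery (fragmentation, indexing,
network, selection logic) under controlled conditions, not performance
claims about any particular compound database.  Full-scale runs on a real
bioactivity export are supported through the same CLI (column mapping for
ChEMBL-style headers) but take hours and are outside the test suite.

## Numerical and design choices

- Geometric-mean aggregation returns the value itself for singletons (exact,
  no exp/log round-trip) and is scale-equivariant.
- All orderings are made deterministic: MMP records sort by (compound_a,
  compound_b, core), series by smallest member, covers by ascending subset
  enumeration over cores sorted by (coverage, string).  Identical input and
  config reproduce byte-identical output tables.
- Attachment points are written as the wildcard atom (`*`); isotope or
  atom-map labels on wildcards are normalised away so `[1*]`, `[*]` and `*`
  fragments compare equal.
- Problem sizes in the tests and the acceptance script (25-series fixtures,
  100 oracle-equivalence sets of ≤ 50 compounds) were chosen as the smallest
  sets that exercise every designed role and boundary; the pipeline itself
  is linear in total fragment pairs and handles repository-scale inputs.

## Known limitations

- The RECAP dialect is a defensible but not unique reading; absolute MMP
  counts on real data shift with dialect choices, which is why the rule set
  is a user-overridable config and fixtures avoid dialect-sensitive rules.
- Only single-cut MMPs are generated; analogs differing at two sites are
  related only through intermediates (this is by definition, not a bug).
- Multi-fragment structures are reduced to their largest covalent component;
  genuine mixtures are therefore conflated with their parent.
- The greedy cover fallback does not guarantee minimality (flagged
  `greedy` in the output); the exact threshold of 20 candidate cores keeps
  worst-case enumeration around 2²⁰ subsets.
- Consensus scaffolds by maximum common substructure for series lacking a
  qualifying core, and the selection of multiple scaffolds per series, are
  deliberate non-goals.
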