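# asbscaffolds

Systematic extraction of **analog series-based (ASB) scaffolds** from tables of
bioactive compounds.

Medicinal chemists organise compounds around scaffolds — core structures shared
by series of analogs.  The classical Bemis–Murcko framework (all rings plus the
linkers between them) is easy to compute but ignores how analogs are actually
made: adding a ring as an R-group changes the framework, and no reaction
information is retained.  The ASB scaffold is an alternative, analog
series-centric definition:

1. **RECAP-MMPs.**  A matched molecular pair (MMP) is two compounds that differ
   by a chemical modification at a single site; it decomposes into a shared
   *core* and two exchanged *substituents*.  Cuts are restricted to
   retrosynthetic (RECAP) bond types — amide, ester, amine, urea, ether,
   olefin, quaternary N, aromatic N–aliphatic C, lactam N–aliphatic C,
   aromatic C–aromatic C, sulfonamide — so every MMP corresponds to a
   plausible chemical reaction.  Size restrictions keep pairs analog-like:
   the larger exchanged substituent may have at most 13 heavy atoms, and the
   core must be at least twice its size.
2. **Analog series.**  Compounds are nodes of a network whose edges are MMP
   relationships; each connected component is one analog series.
3. **Structural key (SK) compounds.**  A member that forms an MMP with every
   other member of its series.
4. **ASB scaffold.**  An MMP core of an SK compound that backs an MMP
   relationship to *every* other analog of the series; if several such cores
   qualify, the largest one (by heavy-atom count) is the scaffold.  When no
   single core qualifies, a minimum set of SK cores jointly covering all
   members (a *core cover*) is reported instead.

Because series are built from curated active compounds, every scaffold is
annotated with the targets its series is active against — single-target
scaffolds are natural candidates for privileged-substructure analysis.

## Worked example

```python
from asbscaffolds.chem_core import make_compound, load_default_rules
from asbscaffolds.mmp_engine import generate_mmps
from asbscaffolds.series_network import build_network, extract_series
from asbscaffolds.asb_scaffold import find_sk_compounds, qualifying_cores, select_asb_scaffold

rules = load_default_rules()
compounds = [
    make_compound("C1", "CNC(=O)c1ccccc1"),    # N-methylbenzamide
    make_compound("C2", "CCNC(=O)c1ccccc1"),   # N-ethylbenzamide
    make_compound("C3", "CCCNC(=O)c1ccccc1"),  # N-propylbenzamide
]
mmps = generate_mmps(compounds, rules)
series = extract_series(build_network(mmps))[0]
sk = find_sk_compounds(series)
scaffold = select_asb_scaffold(qualifying_cores(series, sk), series)
print(len(mmps), sorted(sk.sk_compounds), scaffold.core.structure, scaffold.heavy_atoms)
```

prints

```
3 ['C1', 'C2', 'C3'] *C(=O)c1ccccc1 8
```

The three benzamides form a 3-clique (every pair shares the benzoyl core), so
all three are SK compounds, and the single qualifying core — the benzoyl
fragment with its attachment point, 8 heavy atoms — is the ASB scaffold.
Had the analogs varied at two different sites, no single core would qualify
and `compute_core_cover` would return the minimal set of cores spanning the
series instead.

## Command line

The same pipeline is exposed as a CLI over delimited activity tables
(compound id, SMILES, target, organism, relationship type, confidence score,
measurement type, relation, value, unit — header names remappable via a YAML
config for ChEMBL-style exports):

```
asb-scaffolds simulate --seed 3 --outdir work          # seeded ground-truth fixture
asb-scaffolds run-all --input work/fixture_activity.tsv --outdir work/out
# or stage by stage, auditable intermediates:
asb-scaffolds curate --input ... --outdir out
asb-scaffolds mmp --outdir out
asb-scaffolds series --outdir out
asb-scaffolds scaffold --outdir out
asb-scaffolds stats --outdir out
```

Curation keeps exact ('=') Ki and IC50 measurements against single human
protein targets (direct interaction, highest confidence), converts units to
nM, and aggregates repeated measurements per compound/target/type by
geometric mean provided they span at most one order of magnitude.  Outputs
are TSV tables per stage (curated compounds, MMPs, series assignments, SK
compounds, scaffolds, covers) plus a statistics table of series / compound /
SK / target counts at the three pipeline stages and a manifest with input
hashes and stage counts.

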