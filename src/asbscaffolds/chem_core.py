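"""Structure handling: canonicalization, RECAP single-cut fragmentation, reassembly.

Molecules are carried around as canonical isomeric SMILES.  A fragmentation
cuts exactly one acyclic bond matched by a retrosynthetic (RECAP-style) rule
and yields two fragments, each with a single wildcard-atom attachment point
(``*``).  Because matched molecular pairs are defined by a modification at a
single site, multi-cut fragmentation is deliberately not supported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

__all__ = [
    "Compound",
    "Fragment",
    "FragmentPair",
    "RuleSet",
    "canonicalize",
    "canonicalize_fragment",
    "count_heavy_atoms",
    "enumerate_recap_cuts",
    "load_default_rules",
    "reassemble",
    "strip_to_largest_component",
]


class StructureError(ValueError):
    """Raised when a structure cannot be parsed or processed."""


@dataclass(frozen=True)
class Compound:
    """A unique chemical structure with optional activity annotations.

    ``structure`` is a canonical isomeric SMILES of a single covalently
    connected molecule; ``heavy_atoms`` counts its non-hydrogen atoms.
    """

    compound_id: str
    structure: str
    heavy_atoms: int


@dataclass(frozen=True, order=True)
class Fragment:
    """A one-attachment-point fragment (canonical SMILES with one ``*``)."""

    structure: str
    heavy_atoms: int


@dataclass(frozen=True)
class FragmentPair:
    """One single-cut decomposition of a parent compound.

    Joining ``core`` and ``substituent`` at their attachment points restores
    the parent; heavy atoms are conserved across the cut.
    """

    parent_id: str
    core: Fragment
    substituent: Fragment
    rule_id: str


class RuleSet:
    """Compiled retrosynthetic bond-matching rules.

    Each rule is a SMARTS with atom maps ``:1`` and ``:2`` marking the bond
    to cleave.  Rules are applied in file order; when several rules match
    the same bond the first one names the cut.
    """

    def __init__(self, rules: list[tuple[str, str]]):
        self._compiled: list[tuple[str, Chem.Mol, int, int]] = []
        for rule_id, smarts in rules:
            patt = Chem.MolFromSmarts(smarts)
            if patt is None:
                raise ValueError(f"rule {rule_id!r}: invalid SMARTS {smarts!r}")
            amap = {
                a.GetAtomMapNum(): a.GetIdx()
                for a in patt.GetAtoms()
                if a.GetAtomMapNum()
            }
            if set(amap) < {1, 2}:
                raise ValueError(f"rule {rule_id!r}: needs atom maps :1 and :2")
            self._compiled.append((rule_id, patt, amap[1], amap[2]))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RuleSet":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls([(r["id"], r["smarts"]) for r in doc["rules"]])

    @property
    def rule_ids(self) -> list[str]:
        return [rid for rid, *_ in self._compiled]

    def matching_bonds(self, mol: Chem.Mol) -> dict[int, str]:
        """Map bond index -> rule id for every cleavable acyclic bond."""
        hits: dict[int, str] = {}
        for rule_id, patt, i1, i2 in self._compiled:
            for match in mol.GetSubstructMatches(patt):
                bond = mol.GetBondBetweenAtoms(match[i1], match[i2])
                if bond is None or bond.IsInRing():
                    continue
                hits.setdefault(bond.GetIdx(), rule_id)
        return hits


def load_default_rules() -> RuleSet:
    """The packaged 11-rule RECAP bond set."""
    ref = resources.files("asbscaffolds").joinpath("data/recap_rules.yaml")
    with resources.as_file(ref) as path:
        return RuleSet.from_yaml(path)


def _parse(structure: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise StructureError(f"unparsable structure: {structure!r}")
    return mol


def canonicalize(structure: str) -> str:
    """Canonical isomeric SMILES of a single connected molecule.

    Two notations of the same molecule map to the identical string, and the
    map is idempotent.  Disconnected inputs (salts, mixtures) are rejected:
    strip them first with :func:`strip_to_largest_component`.
    """
    mol = _parse(structure)
    if len(Chem.GetMolFrags(mol)) != 1:
        raise StructureError(f"structure is not a single connected molecule: {structure!r}")
    return Chem.MolToSmiles(mol)


def strip_to_largest_component(structure: str) -> str:
    """Drop counterions/solvents: keep the largest covalent component."""
    mol = _parse(structure)
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) > 1:
        logger.info("stripped %d components from %r", len(frags) - 1, structure)
    best = max(frags, key=lambda m: (m.GetNumHeavyAtoms(), Chem.MolToSmiles(m)))
    return Chem.MolToSmiles(best)


def count_heavy_atoms(structure: str) -> int:
    """Non-hydrogen atoms, excluding wildcard attachment markers."""
    mol = _parse(structure)
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


def canonicalize_fragment(structure: str) -> Fragment:
    """Canonical form of a one-attachment-point fragment SMILES."""
    mol = _parse(structure)
    dummies = [a for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
    if len(dummies) != 1:
        raise StructureError(f"fragment needs exactly one attachment point: {structure!r}")
    # Normalise isotope/map labels on the wildcard so '[1*]' == '[*]' == '*'.
    dummies[0].SetIsotope(0)
    dummies[0].SetAtomMapNum(0)
    smi = Chem.MolToSmiles(mol)
    heavy = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)
    return Fragment(structure=smi, heavy_atoms=heavy)


def make_compound(compound_id: str, structure: str) -> Compound:
    """Canonicalize and wrap a structure; raises StructureError on failure."""
    canon = canonicalize(structure)
    return Compound(compound_id, canon, count_heavy_atoms(canon))


def enumerate_recap_cuts(compound: Compound, rules: RuleSet) -> set[FragmentPair]:
    """All single-cut decompositions of a compound under the rule set.

    Every distinct acyclic bond matching a rule is cut once, and the two
    resulting fragments are emitted in BOTH orientations (each side once as
    core, once as substituent).  Duplicate decompositions arising from
    molecular symmetry collapse because FragmentPair equality is by
    canonical fragment strings.  Molecules without cleavable bonds yield an
    empty set.
    """
    mol = _parse(compound.structure)
    pairs: set[FragmentPair] = set()
    for bond_idx, rule_id in sorted(rules.matching_bonds(mol).items()):
        cut = Chem.FragmentOnBonds(mol, [bond_idx], addDummies=True, dummyLabels=[(0, 0)])
        try:
            halves = Chem.GetMolFrags(cut, asMols=True, sanitizeFrags=True)
        except Exception:  # pragma: no cover - sanitization failure on exotic input
            logger.warning("cut of bond %d in %s failed sanitization", bond_idx, compound.structure)
            continue
        if len(halves) != 2:
            continue
        fa = canonicalize_fragment(Chem.MolToSmiles(halves[0]))
        fb = canonicalize_fragment(Chem.MolToSmiles(halves[1]))
        pairs.add(FragmentPair(compound.compound_id, core=fa, substituent=fb, rule_id=rule_id))
        pairs.add(FragmentPair(compound.compound_id, core=fb, substituent=fa, rule_id=rule_id))
    return pairs


def reassemble(core: Fragment | str, substituent: Fragment | str) -> str:
    """Join two fragments at their attachment points; canonical SMILES result.

    The two attachment bonds must have the same order (single for every
    rule except the olefin cut, which restores a double bond).
    """
    smi_a = core.structure if isinstance(core, Fragment) else core
    smi_b = substituent.structure if isinstance(substituent, Fragment) else substituent
    combined = Chem.RWMol(Chem.CombineMols(_parse(smi_a), _parse(smi_b)))
    dummies = [a.GetIdx() for a in combined.GetAtoms() if a.GetAtomicNum() == 0]
    if len(dummies) != 2:
        raise StructureError("reassembly needs exactly one attachment point per fragment")
    neighbors = []
    orders = []
    for d in dummies:
        atom = combined.GetAtomWithIdx(d)
        nbrs = atom.GetNeighbors()
        if len(nbrs) != 1:
            raise StructureError("attachment marker must have exactly one neighbor")
        neighbors.append(nbrs[0].GetIdx())
        orders.append(combined.GetBondBetweenAtoms(d, nbrs[0].GetIdx()).GetBondType())
    if orders[0] != orders[1]:
        raise StructureError("attachment bond orders differ between fragments")
    combined.AddBond(neighbors[0], neighbors[1], orders[0])
    for d in sorted(dummies, reverse=True):
        combined.RemoveAtom(d)
    product = combined.GetMol()
    Chem.SanitizeMol(product)
    return Chem.MolToSmiles(product)
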