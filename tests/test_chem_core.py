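"""Canonicalization, retrosynthetic single-cut fragmentation, reassembly."""

import pytest
from rdkit import Chem

from asbscaffolds.chem_core import (
    StructureError,
    canonicalize,
    canonicalize_fragment,
    count_heavy_atoms,
    enumerate_recap_cuts,
    make_compound,
    reassemble,
    strip_to_largest_component,
)


class TestCanonicalize:
    @pytest.mark.parametrize(
        "a,b",
        [
            ("C(C)N", "CCN"),
            ("c1ccccc1C(=O)NC", "CNC(=O)c1ccccc1"),
            ("OCC", "CCO"),
        ],
    )
    def test_notations_of_same_molecule_agree(self, a, b):
        assert canonicalize(a) == canonicalize(b)

    def test_idempotent(self):
        once = canonicalize("CCNC(=O)c1ccccc1")
        assert canonicalize(once) == once

    def test_matches_toolkit_graph_identity(self):
        # independent oracle: RDKit graph isomorphism via substructure match
        a = Chem.MolFromSmiles("c1ccccc1C(=O)NC")
        b = Chem.MolFromSmiles("CNC(=O)c1ccccc1")
        assert a.HasSubstructMatch(b) and b.HasSubstructMatch(a)
        assert canonicalize("c1ccccc1C(=O)NC") == canonicalize("CNC(=O)c1ccccc1")

    def test_parse_failure_raises(self):
        with pytest.raises(StructureError):
            canonicalize("not_a_smiles((")

    def test_disconnected_rejected_and_salt_strip(self):
        with pytest.raises(StructureError):
            canonicalize("CCN.Cl")
        assert strip_to_largest_component("CCN.Cl") == canonicalize("CCN")

    def test_stereoisomers_stay_distinct(self):
        assert canonicalize("C/C=C/C") != canonicalize("C/C=C\\C")


class TestHeavyAtoms:
    @pytest.mark.parametrize(
        "fragment,expected",
        [("[*]NC", 2), ("[*]C(=O)c1ccccc1", 8), ("[*]N", 1), ("[*]Oc1ccccc1C(=O)NC", 11)],
    )
    def test_counts_exclude_attachment_marker(self, fragment, expected):
        frag = canonicalize_fragment(fragment)
        assert frag.heavy_atoms == expected
        assert count_heavy_atoms(fragment) == expected

    def test_fragment_needs_exactly_one_attachment(self):
        with pytest.raises(StructureError):
            canonicalize_fragment("CCN")
        with pytest.raises(StructureError):
            canonicalize_fragment("[*]C([*])N")

    def test_attachment_label_variants_collapse(self):
        assert canonicalize_fragment("[1*]NC") == canonicalize_fragment("*NC")


class TestEnumerateRecapCuts:
    def test_benzamide_single_amide_cut_both_orientations(self, rules):
        comp = make_compound("x", "CNC(=O)c1ccccc1")
        pairs = enumerate_recap_cuts(comp, rules)
        assert {(p.core.structure, p.substituent.structure) for p in pairs} == {
            (canonicalize_fragment("[*]C(=O)c1ccccc1").structure, canonicalize_fragment("[*]NC").structure),
            (canonicalize_fragment("[*]NC").structure, canonicalize_fragment("[*]C(=O)c1ccccc1").structure),
        }
        assert all(p.rule_id == "amide" for p in pairs)

    def test_benzene_has_no_cleavable_bond(self, rules):
        assert enumerate_recap_cuts(make_compound("x", "c1ccccc1"), rules) == set()

    def test_two_site_molecule_yields_two_bonds_four_pairs(self, rules):
        pairs = enumerate_recap_cuts(make_compound("x", "COc1ccccc1C(=O)NC"), rules)
        assert len(pairs) == 4
        assert {p.rule_id for p in pairs} == {"ether", "amide"}

    def test_symmetry_equivalent_cuts_collapse(self, rules):
        # triethylamine: three equivalent N-C bonds, one distinct decomposition
        pairs = enumerate_recap_cuts(make_compound("x", "CCN(CC)CC"), rules)
        assert {(p.core.structure, p.substituent.structure) for p in pairs} == {
            (canonicalize_fragment("[*]N(CC)CC").structure, canonicalize_fragment("[*]CC").structure),
            (canonicalize_fragment("[*]CC").structure, canonicalize_fragment("[*]N(CC)CC").structure),
        }

    def test_ring_bonds_never_cut(self, rules):
        # lactam: the in-ring amide bond must not be cut, the exocyclic N-C must
        pairs = enumerate_recap_cuts(make_compound("x", "CN1CCCC1=O"), rules)
        assert {p.rule_id for p in pairs} == {"lactam_n_aliphatic_c"}
        assert len(pairs) == 2

    @pytest.mark.parametrize(
        "smiles,expected_rules",
        [
            ("CCOC(=O)c1ccccc1", {"ester"}),
            ("CNC(=O)NC", {"urea"}),
            ("CNS(=O)(=O)c1ccccc1", {"sulfonamide"}),
            ("Cn1cccc1", {"aromatic_n_aliphatic_c"}),
            ("c1ccc(-c2ccncc2)cc1", {"aromatic_c_aromatic_c"}),
            ("C[N+](C)(C)C", {"quaternary_n"}),
            ("CC=Cc1ccccc1", {"olefin"}),
        ],
    )
    def test_rule_dialect_assignments(self, rules, smiles, expected_rules):
        pairs = enumerate_recap_cuts(make_compound("x", smiles), rules)
        assert {p.rule_id for p in pairs} == expected_rules

    def test_amide_nitrogen_alkyl_bond_is_not_an_amine_bond(self, rules):
        # critical dialect choice: N-methylbenzamide has ONE cleavable bond
        pairs = enumerate_recap_cuts(make_compound("x", "CNC(=O)c1ccccc1"), rules)
        assert len(pairs) == 2  # one bond, two orientations


class TestRoundTrips:
    @pytest.mark.parametrize(
        "smiles",
        [
            "CNC(=O)c1ccccc1",
            "COc1ccccc1C(=O)NC",
            "CCOC(=O)c1cccc2ccccc12",
            "CNS(=O)(=O)c1ccccc1",
            "CC=Cc1ccccc1",
            "c1ccc(-c2ccncc2)cc1",
            "CN1CCCC1=O",
            "CCN(CC)CC",
            "CNC(=O)NCc1ccccc1",
        ],
    )
    def test_reassembly_restores_parent_and_conserves_atoms(self, rules, smiles):
        comp = make_compound("x", smiles)
        pairs = enumerate_recap_cuts(comp, rules)
        assert pairs
        for p in pairs:
            assert reassemble(p.core, p.substituent) == comp.structure
            assert p.core.heavy_atoms + p.substituent.heavy_atoms == comp.heavy_atoms
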