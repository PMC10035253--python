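import pytest
from rdkit import Chem

from glycosmiles.errors import (
    DuplicatePositionError,
    NoDefaultPositionError,
    UndetachableError,
)
from glycosmiles.glycan_ast import Anomer, ModAction, ModificationSpec, Site
from glycosmiles.modifications import (
    FRAGMENTS,
    apply_modification,
    apply_modification_chain,
    resolve_default_position,
)
from glycosmiles.monomers import lookup_template


def spec(token, pos=None):
    frag = FRAGMENTS[token]
    return ModificationSpec(token, pos, frag.site_class, frag.action)


def inchi(template):
    return Chem.MolToInchi(Chem.MolFromSmiles(template.to_smiles()))


class TestFragmentTable:
    def test_every_splice_body_caps_to_a_valid_molecule(self):
        for frag in FRAGMENTS.values():
            if frag.smiles_body is None:
                continue
            assert Chem.MolFromSmiles(frag.smiles_body) is not None, frag.token

    def test_delete_token_has_delete_action(self):
        assert FRAGMENTS["d"].action is ModAction.DELETE


class TestDefaults:
    def test_nac_defaults_to_carbon_2(self):
        assert resolve_default_position(spec("NAc"), "Gal").position == 2

    def test_acetyl_defaults_to_5_on_sialic_acids(self):
        assert resolve_default_position(spec("Ac"), "Neu").position == 5

    def test_uronate_defaults_to_the_terminal_carbon(self):
        assert resolve_default_position(spec("A"), "Glc").position == 6

    def test_sulfate_has_no_default(self):
        with pytest.raises(NoDefaultPositionError):
            resolve_default_position(spec("S"), "Man")


class TestApply:
    def test_sulfate_on_mannose_c3(self):
        t = lookup_template("Man", Anomer.ALPHA)
        apply_modification(t, spec("S", 3))
        mol = Chem.MolFromSmiles(t.to_smiles())
        assert mol.HasSubstructMatch(Chem.MolFromSmarts("OS(=O)(=O)O"))
        assert t.formula() == "C6H12O9S"

    def test_deoxy_glucose_matches_printed_structure(self):
        t = lookup_template("Glc", Anomer.UNSPECIFIED)
        apply_modification(t, spec("d", 2))
        ref = Chem.MolToInchi(Chem.MolFromSmiles(
            "OC[C@H]1OC(O)C[C@@H](O)[C@@H]1O"))
        assert inchi(t) == ref

    def test_deoxy_on_already_deoxy_carbon_is_undetachable(self):
        t = lookup_template("Dig", Anomer.UNSPECIFIED)
        with pytest.raises(UndetachableError):
            apply_modification(t, spec("d", 2))

    def test_deoxy_at_anomeric_position_is_undetachable(self):
        t = lookup_template("Glc", Anomer.ALPHA)
        with pytest.raises(UndetachableError):
            apply_modification(t, spec("d", 1))

    def test_n_acetyl_replaces_the_c2_hydroxyl(self):
        t = lookup_template("Gal", Anomer.ALPHA)
        apply_modification(t, spec("NAc"))  # default position 2
        assert t.formula() == "C8H15NO6"  # GalNAc
        mol = Chem.MolFromSmiles(t.to_smiles())
        match = mol.GetSubstructMatches(Chem.MolFromSmarts("[NX3][CX3](=O)[CH3]"))
        assert len(match) == 1
        # the amide N sits on carbon 2
        c2 = t.carbon_idx(2)
        assert any(c2 == nb.GetIdx()
                   for nb in t.mol.GetAtomWithIdx(
                       t.attachment(2)[0]).GetNeighbors())
        assert t.attachment(2)[1] is Site.N

    def test_acetyl_on_existing_amine_acylates_in_place(self):
        t = lookup_template("Neu", Anomer.ALPHA)
        apply_modification(t, spec("Ac"))  # -> Neu5Ac
        assert t.formula() == "C11H19NO9"

    def test_uronate_oxidation_gives_glucuronic_acid(self):
        t = lookup_template("Glc", Anomer.ALPHA)
        apply_modification(t, spec("A"))
        assert t.formula() == "C6H10O7"
        mol = Chem.MolFromSmiles(t.to_smiles())
        assert mol.HasSubstructMatch(Chem.MolFromSmarts("C(=O)[OX2H1]"))


class TestChains:
    def test_sulfate_and_phosphate_coexist(self):
        t = lookup_template("Man", Anomer.ALPHA)
        apply_modification_chain(t, [spec("S", 3), spec("P", 4)])
        mol = Chem.MolFromSmiles(t.to_smiles())
        assert mol.HasSubstructMatch(Chem.MolFromSmarts("OS(=O)(=O)O"))
        assert mol.HasSubstructMatch(Chem.MolFromSmarts("OP(=O)(O)O"))

    def test_splices_at_distinct_positions_commute(self):
        a = lookup_template("Man", Anomer.ALPHA)
        apply_modification_chain(a, [spec("S", 3), spec("P", 4)])
        b = lookup_template("Man", Anomer.ALPHA)
        apply_modification_chain(b, [spec("P", 4), spec("S", 3)])
        assert inchi(a) == inchi(b)

    def test_empty_chain_is_identity(self):
        t = lookup_template("Man", Anomer.ALPHA)
        before = t.to_smiles()
        apply_modification_chain(t, [])
        assert t.to_smiles() == before

    def test_same_position_twice_is_rejected(self):
        t = lookup_template("Man", Anomer.ALPHA)
        with pytest.raises(DuplicatePositionError):
            apply_modification_chain(t, [spec("S", 2), spec("P", 2)])

    def test_no_sentinels_survive_and_valences_hold(self):
        t = lookup_template("Glc", Anomer.BETA)
        apply_modification_chain(t, [spec("NAc", 2), spec("S", 6)])
        smi = t.to_smiles()
        mol = Chem.MolFromSmiles(smi)
        assert mol is not None
        assert all(a.GetAtomicNum() <= 53 for a in mol.GetAtoms())

    def test_stereocenters_away_from_the_edit_are_untouched(self):
        # chiral parity flags are atom-order-relative, so compare the
        # order-independent CIP labels of the untouched carbons instead
        def cip_labels(template):
            mol = Chem.Mol(template.mol)
            Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
            return {a.GetAtomMapNum(): a.GetPropsAsDict().get("_CIPCode")
                    for a in mol.GetAtoms()
                    if a.GetAtomMapNum() in (1, 3, 4, 5)}

        t = lookup_template("Gal", Anomer.ALPHA)
        before = cip_labels(t)
        apply_modification(t, spec("S", 2))
        assert cip_labels(t) == before
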