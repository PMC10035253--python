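import pytest
from rdkit import Chem

from glycosmiles.errors import (
    DuplicatePositionError,
    UnknownModificationError,
    UnknownMonomerError,
)
from glycosmiles.glycan_ast import Anomer, Enantiomer, RingForm
from glycosmiles.monomers import (
    INVENTORY,
    inventory,
    lookup_template,
    split_monomer_token,
)


def inchi(template):
    return Chem.MolToInchi(Chem.MolFromSmiles(template.to_smiles()))


class TestInventory:
    def test_at_least_59_base_names(self):
        assert len(INVENTORY) >= 59

    def test_every_template_builds_valence_valid(self):
        for rec in inventory():
            for anomer in (Anomer.ALPHA, Anomer.BETA, Anomer.UNSPECIFIED):
                t = lookup_template(rec.name, anomer)
                mol = Chem.MolFromSmiles(t.to_smiles())
                assert mol is not None, (rec.name, anomer)

    def test_position_map_is_unique_and_complete(self):
        for rec in inventory():
            t = lookup_template(rec.name)
            seen = {}
            for atom in t.mol.GetAtoms():
                if atom.GetAtomMapNum():
                    assert atom.GetAtomMapNum() not in seen
                    seen[atom.GetAtomMapNum()] = atom.GetIdx()
            assert set(seen) == set(range(1, rec.n_carbons + 1)), rec.name

    def test_exactly_one_ring_with_one_ring_oxygen(self):
        for rec in inventory():
            t = lookup_template(rec.name, Anomer.ALPHA)
            ri = t.mol.GetRingInfo()
            assert ri.NumRings() == 1, rec.name
            ring = ri.AtomRings()[0]
            assert len(ring) in (5, 6), rec.name
            ring_os = [i for i in ring
                       if t.mol.GetAtomWithIdx(i).GetAtomicNum() == 8]
            assert len(ring_os) == 1, rec.name

    def test_one_anomeric_carbon_bonded_to_two_oxygens(self):
        for rec in inventory():
            t = lookup_template(rec.name, Anomer.ALPHA)
            cidx = t.carbon_idx(t.anomeric_position)
            carbon = t.mol.GetAtomWithIdx(cidx)
            n_ox = sum(nb.GetAtomicNum() == 8 for nb in carbon.GetNeighbors())
            assert n_ox >= 2, rec.name


class TestStereochemistry:
    def test_alpha_d_glucopyranose_matches_the_textbook_smiles(self):
        t = lookup_template("Glc", Anomer.ALPHA)
        ref = Chem.CanonSmiles("OC[C@H]1O[C@H](O)[C@H](O)[C@@H](O)[C@@H]1O")
        assert t.to_smiles() == ref

    @pytest.mark.parametrize("name,ref", [
        ("Glc", "OC[C@H]1O[C@@H](O)[C@H](O)[C@@H](O)[C@@H]1O"),
        ("Man", "OC[C@H]1O[C@@H](O)[C@@H](O)[C@@H](O)[C@@H]1O"),
        ("Gal", "OC[C@H]1O[C@@H](O)[C@H](O)[C@@H](O)[C@H]1O"),
    ])
    def test_beta_d_hexopyranoses(self, name, ref):
        t = lookup_template(name, Anomer.BETA)
        assert t.to_smiles() == Chem.CanonSmiles(ref)

    def test_alpha_and_beta_differ_only_at_the_anomeric_carbon(self):
        for name in ("Glc", "Man", "Gal", "Fuc", "Xyl", "Fru"):
            pair = []
            for anomer in (Anomer.ALPHA, Anomer.BETA):
                t = lookup_template(name, anomer)
                cidx = t.carbon_idx(t.anomeric_position)
                t.mol.GetAtomWithIdx(cidx).SetChiralTag(
                    Chem.ChiralType.CHI_UNSPECIFIED)
                pair.append(t.to_smiles())
            assert pair[0] == pair[1], name

    def test_l_sugar_is_the_mirror_image(self):
        d = lookup_template("Glc", Anomer.ALPHA, enantiomer=Enantiomer.D)
        l = lookup_template("Glc", Anomer.ALPHA, enantiomer=Enantiomer.L)
        dk = Chem.MolToInchiKey(Chem.MolFromSmiles(d.to_smiles()))
        lk = Chem.MolToInchiKey(Chem.MolFromSmiles(l.to_smiles()))
        assert dk != lk
        assert dk.split("-")[0] == lk.split("-")[0]  # same constitution

    def test_epimers_share_constitution_but_not_configuration(self):
        keys = set()
        first_blocks = set()
        for name in ("Glc", "Man", "Gal", "All", "Alt", "Gul", "Ido", "Tal"):
            t = lookup_template(name, Anomer.ALPHA, enantiomer=Enantiomer.D)
            key = Chem.MolToInchiKey(Chem.MolFromSmiles(t.to_smiles()))
            keys.add(key)
            first_blocks.add(key.split("-")[0])
        assert len(keys) == 8          # all eight aldohexoses are distinct
        assert len(first_blocks) == 1  # yet the same atom graph

    def test_synonyms_share_the_atom_graph(self):
        for syn, canon in [("AraHex", "Glc"), ("LyxHex", "Gal"),
                           ("RibHex", "All"), ("XylHex", "Gul")]:
            assert inchi(lookup_template(syn, Anomer.ALPHA)) == \
                inchi(lookup_template(canon, Anomer.ALPHA))

    def test_generic_hexose_has_wildcard_stereocenters(self):
        t = lookup_template("Hex", Anomer.UNSPECIFIED)
        assert "@" not in t.to_smiles()


class TestFormulas:
    @pytest.mark.parametrize("name,formula", [
        ("Glc", "C6H12O6"), ("Man", "C6H12O6"), ("Tal", "C6H12O6"),
        ("Xyl", "C5H10O5"), ("Ara", "C5H10O5"),
        ("Fru", "C6H12O6"), ("Api", "C5H10O5"),
        ("Fuc", "C6H12O5"), ("Rha", "C6H12O5"), ("Qui", "C6H12O5"),
        ("Dig", "C6H12O4"), ("Abe", "C6H12O4"),
        ("Neu", "C9H17NO8"), ("Kdn", "C9H16O9"), ("Kdo", "C8H14O8"),
        ("Mur", "C9H17NO7"), ("Bac", "C6H14N2O3"),
        ("LDManHep", "C7H14O7"), ("Ery", "C4H8O4"),
    ])
    def test_template_molecular_formulas(self, name, formula):
        assert lookup_template(name, Anomer.ALPHA).formula() == formula


class TestTemplateLookup:
    def test_returns_independently_mutable_copies(self):
        a = lookup_template("Man", Anomer.ALPHA)
        b = lookup_template("Man", Anomer.ALPHA)
        a.mol.GetAtomWithIdx(0).SetAtomicNum(7)
        assert b.mol.GetAtomWithIdx(0).GetAtomicNum() != 7 or \
            a.to_smiles() != b.to_smiles()

    def test_unspecified_anomer_has_untagged_anomeric_carbon(self):
        t = lookup_template("Glc", Anomer.UNSPECIFIED)
        cidx = t.carbon_idx(1)
        assert t.mol.GetAtomWithIdx(cidx).GetChiralTag() == \
            Chem.ChiralType.CHI_UNSPECIFIED

    def test_unknown_name_raises(self):
        with pytest.raises(UnknownMonomerError):
            lookup_template("Xyz", Anomer.ALPHA)

    def test_ring_form_override(self):
        p = lookup_template("Gal", Anomer.BETA, RingForm.PYRANOSE)
        f = lookup_template("Gal", Anomer.BETA, RingForm.FURANOSE)
        assert p.mol.GetRingInfo().AtomRings()[0].__len__() == 6
        assert f.mol.GetRingInfo().AtomRings()[0].__len__() == 5


class TestTokenSplitting:
    def test_deoxy_prefix(self):
        base, mods, _, _ = split_monomer_token("6dTal")
        assert base == "Tal"
        assert [(m.token, m.position) for m in mods] == [("d", 6)]

    def test_default_position_token(self):
        base, mods, _, _ = split_monomer_token("GalNAc")
        assert base == "Gal"
        assert [(m.token, m.position) for m in mods] == [("NAc", None)]

    def test_multiple_suffix_modifications_keep_order(self):
        base, mods, _, _ = split_monomer_token("Man3S4P")
        assert base == "Man"
        assert [(m.token, m.position) for m in mods] == [("S", 3), ("P", 4)]

    def test_bare_base(self):
        assert split_monomer_token("Man")[:2] == ("Man", [])

    def test_duplicate_explicit_positions_rejected(self):
        with pytest.raises(DuplicatePositionError):
            split_monomer_token("Man2S2P")

    def test_longest_name_wins(self):
        assert split_monomer_token("AraHex")[0] == "AraHex"
        assert split_monomer_token("Ara")[0] == "Ara"
        assert split_monomer_token("2dAraHex")[1][0].position == 2

    def test_ring_and_enantiomer_affixes(self):
        base, mods, ring, enant = split_monomer_token("L-Fucp2S")
        assert (base, ring, enant) == ("Fuc", RingForm.PYRANOSE, Enantiomer.L)
        assert [(m.token, m.position) for m in mods] == [("S", 2)]

    def test_unknown_parts_raise(self):
        with pytest.raises(UnknownMonomerError):
            split_monomer_token("Zzz3S")
        with pytest.raises(UnknownModificationError):
            split_monomer_token("Man3Q")
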