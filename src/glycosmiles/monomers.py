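"""Monosaccharide template library.

Templates are stereochemically annotated RDKit molecules in which every
backbone carbon carries an atom-map number equal to its IUPAC carbon index
(C1, C2, ...).  That makes position -> atom lookup O(1) and keeps all later
per-carbon surgery (modifications, glycosidic attachment) local.

Template construction is systematic rather than a list of hand-typed
SMILES.  A sugar is described by its family (aldose/ketose, ring size,
chain length) plus a Fischer-projection configuration pattern — ``R`` for a
hydroxyl drawn on the right, ``L`` for the left.  The writer emits a SMILES
skeleton in a fixed atom order, so each ring slot has one constant chirality
tag meaning "Fischer right"; epimers and enantiomers are pure tag algebra
(an L-sugar is the full mirror image, which also inverts the geometric
meaning of alpha/beta).  The constants are calibrated against
alpha-D-glucopyranose, OC[C@H]1O[C@H](O)[C@H](O)[C@@H](O)[C@@H]1O, and
beta-D-fructofuranose, OC[C@H]1O[C@](O)(CO)[C@@H](O)[C@@H]1O.

The inventory covers 60 base names: the eight aldohexoses, the aldopentoses
and -tetroses, the common ketoses, the named deoxy, amino-deoxy and
O-methyl sugars, LPS heptoses, the ulosonic/sialic acids, apiose and
muramic acid, generic Hex/Pen/Hep/dHex/ddHex wildcards, and the
descriptor-hexose synonyms (AraHex and friends) which map onto the same
atom graph as their canonical names, so e.g. 2dAraHex and 2dGlc compile to
one and the same SMILES.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable

from rdkit import Chem

from .errors import (
    DuplicatePositionError,
    UnknownModificationError,
    UnknownMonomerError,
    UnsupportedFeatureError,
)
from .glycan_ast import Anomer, Enantiomer, ModificationSpec, RingForm, Site

__all__ = [
    "MonomerTemplate",
    "lookup_template",
    "split_monomer_token",
    "inventory",
    "inventory_names",
    "write_inventory_tsv",
]

# ---------------------------------------------------------------------------
# chirality-tag constants (meaning: "Fischer right" in the written skeleton)

_SLOT0_RIGHT = "@"    # highest ring carbon (C5 of a hexopyranose); D at this center
_MID_RIGHT = "@"      # interior ring carbons written mid-string
_LAST_RIGHT = "@@"    # last-written ring carbon (closes the ring digit)
_SIDE_RIGHT = "@"     # exocyclic side-chain stereocenters (heptoses, furanose hexoses)
_ALDO_ANOMER_ALPHA_D = "@"
_KETO_ANOMER_BETA_D = "@"


def _flip(tag: str) -> str:
    return {"@": "@@", "@@": "@", "": ""}[tag]


def _tag(sense: str | None, right_tag: str, mirror: bool) -> str:
    if sense is None:
        return ""
    t = right_tag if sense == "R" else _flip(right_tag)
    return _flip(t) if mirror else t


def _anomeric_tag(anomer: Anomer, base_tag: str, base_is: Anomer, mirror: bool) -> str:
    if anomer is Anomer.UNSPECIFIED:
        return ""
    t = base_tag if anomer is base_is else _flip(base_tag)
    return _flip(t) if mirror else t


# ---------------------------------------------------------------------------
# skeleton writers


def _aldose_smiles(
    n: int,
    ring_size: int,
    senses: dict[int, str | None],
    anomer: Anomer,
    mirror: bool,
    deoxy: frozenset[int] = frozenset(),
    amino: frozenset[int] = frozenset(),
    branches: dict[int, str] | None = None,
) -> str:
    """Aldose with ring carbons C1..C(ring_size-1) and a C tail up to Cn."""

    rmax = ring_size - 1  # highest ring carbon index
    branches = branches or {}

    def branch_of(k: int) -> str | None:
        if k in deoxy:
            return None
        if k in amino:
            return "N"
        return branches.get(k, "O")

    parts: list[str] = []
    # exocyclic tail, outermost atom first
    for k in range(n, rmax, -1):
        if k == n:
            parts.append(f"[CH3:{k}]" if k in deoxy else f"O[CH2:{k}]")
        else:
            b = branch_of(k)
            if b is None:
                parts.append(f"[CH2:{k}]")
            else:
                parts.append(f"[C{_tag(senses.get(k), _SIDE_RIGHT, mirror)}H:{k}]({b})")
    # ring-opening carbon (no hydroxyl: the ring oxygen replaces it)
    if n == rmax:
        parts.append(f"[CH2:{rmax}]1")
    else:
        parts.append(f"[C{_tag(senses.get(rmax), _SLOT0_RIGHT, mirror)}H:{rmax}]1")
    parts.append("O")  # ring oxygen
    # anomeric carbon, always with its hemiacetal hydroxyl
    at = _anomeric_tag(anomer, _ALDO_ANOMER_ALPHA_D, Anomer.ALPHA, mirror)
    parts.append(f"[C{at}H:1](O)")
    # interior ring carbons C2 .. rmax-2
    for k in range(2, rmax - 1):
        b = branch_of(k)
        if b is None:
            parts.append(f"[CH2:{k}]")
        else:
            parts.append(f"[C{_tag(senses.get(k), _MID_RIGHT, mirror)}H:{k}]({b})")
    # last ring carbon closes the ring
    k = rmax - 1
    b = branch_of(k)
    if b is None:
        parts.append(f"[CH2:{k}]1")
    else:
        parts.append(f"[C{_tag(senses.get(k), _LAST_RIGHT, mirror)}H:{k}]1{b}")
    return "".join(parts)


def _ketose_smiles(
    n: int,
    ring_size: int,
    senses: dict[int, str | None],
    anomer: Anomer,
    mirror: bool,
) -> str:
    """2-ketose: ring carbons C2..C(ring_size), exocyclic C1 and tail to Cn."""

    rmax = ring_size  # highest ring carbon index (C5 furanose, C6 pyranose)
    parts: list[str] = []
    for k in range(n, rmax, -1):
        if k == n:
            parts.append(f"O[CH2:{k}]")
        else:
            parts.append(f"[C{_tag(senses.get(k), _SIDE_RIGHT, mirror)}H:{k}](O)")
    if n == rmax:
        parts.append(f"[CH2:{rmax}]1")
    else:
        parts.append(f"[C{_tag(senses.get(rmax), _SLOT0_RIGHT, mirror)}H:{rmax}]1")
    parts.append("O")
    at = _anomeric_tag(anomer, _KETO_ANOMER_BETA_D, Anomer.BETA, mirror)
    parts.append(f"[C{at}:2](O)([CH2:1]O)")
    for k in range(3, rmax - 1):
        parts.append(f"[C{_tag(senses.get(k), _MID_RIGHT, mirror)}H:{k}](O)")
    k = rmax - 1
    parts.append(f"[C{_tag(senses.get(k), _LAST_RIGHT, mirror)}H:{k}]1O")
    return "".join(parts)


def _nonulosonic_smiles(
    anomer: Anomer,
    mirror: bool,
    x5: str = "N",
    x7: str = "O",
    deoxy9: bool = False,
    flips: frozenset[int] = frozenset(),
) -> str:
    """Nonulosonic (sialic-type) pyranose: COOH at C1, anomeric C2, 3-deoxy
    ring, substituent at C5, glycerol-like C7-C9 tail.

    Baseline tags reproduce alpha-neuraminic acid
    (N[C@@H]1[C@@H](O)C[C@@](O)(C(=O)O)O[C@H]1[C@H](O)[C@H](O)CO); rarer
    members (Leg, Pse, Aci) are derived by descriptor arithmetic — flipping
    the listed centers — which is a best-effort assignment.
    """

    tags = {2: "@@", 4: "@@", 5: "@@", 6: "@", 7: "@", 8: "@"}
    if anomer is Anomer.UNSPECIFIED:
        tags[2] = ""
    elif anomer is Anomer.BETA:
        tags[2] = _flip(tags[2])
    for k in flips:
        tags[k] = _flip(tags[k])
    if mirror:
        tags = {k: _flip(t) for k, t in tags.items()}
    tail9 = "[CH3:9]" if deoxy9 else "[CH2:9]O"
    c2 = f"[C{tags[2]}:2]" if tags[2] else "[C:2]"
    return (
        f"{x5}[C{tags[5]}H:5]1[C{tags[4]}H:4](O)[CH2:3]"
        f"{c2}(O)([C:1](O)=O)O[C{tags[6]}H:6]1"
        f"[C{tags[7]}H:7]({x7})[C{tags[8]}H:8](O){tail9}"
    )


def _kdo_like_smiles(anomer: Anomer, mirror: bool, c3_oh: bool = False) -> str:
    """Oct-2-ulosonic pyranose (Kdo; Ko carries a 3-OH)."""
    tags = {2: "@@", 4: "@", 5: "@", 6: "@", 7: "@@"}
    if anomer is Anomer.UNSPECIFIED:
        tags[2] = ""
    elif anomer is Anomer.BETA:
        tags[2] = _flip(tags[2])
    if mirror:
        tags = {k: _flip(t) for k, t in tags.items()}
    c3 = "[CH:3](O)" if c3_oh else "[CH2:3]"
    c2 = f"[C{tags[2]}:2]" if tags[2] else "[C:2]"
    return (
        f"O[CH2:8][C{tags[7]}H:7](O)[C{tags[6]}H:6]1O"
        f"{c2}(O)([C:1](O)=O){c3}[C{tags[4]}H:4](O)[C{tags[5]}H:5]1O"
    )


def _dha_smiles(anomer: Anomer, mirror: bool) -> str:
    """3-deoxy-lyxo-hept-2-ulosaric pyranose (two carboxyls)."""
    tags = {2: "@@", 4: "@", 5: "@@", 6: "@"}
    if anomer is Anomer.UNSPECIFIED:
        tags[2] = ""
    elif anomer is Anomer.BETA:
        tags[2] = _flip(tags[2])
    if mirror:
        tags = {k: _flip(t) for k, t in tags.items()}
    c2 = f"[C{tags[2]}:2]" if tags[2] else "[C:2]"
    return (
        f"O[C:7](=O)[C{tags[6]}H:6]1O"
        f"{c2}(O)([C:1](O)=O)[CH2:3][C{tags[4]}H:4](O)[C{tags[5]}H:5]1O"
    )


def _apiose_smiles(anomer: Anomer, mirror: bool) -> str:
    """3-C-(hydroxymethyl) branched furanose; the branch carbon is mapped 5."""
    t3, t2 = "@", "@@"
    at = _anomeric_tag(anomer, _ALDO_ANOMER_ALPHA_D, Anomer.ALPHA, mirror)
    if mirror:
        t3, t2 = _flip(t3), _flip(t2)
    c1 = f"[C{at}H:1](O)" if at else "[CH:1](O)"
    return f"O[CH2:5][C{t3}:3]1(O)[CH2:4]O{c1}[C{t2}H:2]1O"


# ---------------------------------------------------------------------------
# Fischer configuration patterns (as the D-enantiomer)

_HEXOSES = {
    "All": {2: "R", 3: "R", 4: "R", 5: "R"},
    "Alt": {2: "L", 3: "R", 4: "R", 5: "R"},
    "Glc": {2: "R", 3: "L", 4: "R", 5: "R"},
    "Man": {2: "L", 3: "L", 4: "R", 5: "R"},
    "Gul": {2: "R", 3: "R", 4: "L", 5: "R"},
    "Ido": {2: "L", 3: "R", 4: "L", 5: "R"},
    "Gal": {2: "R", 3: "L", 4: "L", 5: "R"},
    "Tal": {2: "L", 3: "L", 4: "L", 5: "R"},
}
_PENTOSES = {
    "Rib": {2: "R", 3: "R", 4: "R"},
    "Ara": {2: "L", 3: "R", 4: "R"},
    "Xyl": {2: "R", 3: "L", 4: "R"},
    "Lyx": {2: "L", 3: "L", 4: "R"},
}
_TETROSES = {"Ery": {2: "R", 3: "R"}, "Thre": {2: "L", 3: "R"}}
_KETOHEXOSES = {
    "Psi": {3: "R", 4: "R", 5: "R"},
    "Fru": {3: "L", 4: "R", 5: "R"},
    "Sor": {3: "R", 4: "L", 5: "R"},
    "Tag": {3: "L", 4: "L", 5: "R"},
}
_KETOPENTOSES = {"Rul": {3: "R", 4: "R"}, "Xul": {3: "L", 4: "R"}}
_BLANK6 = {2: None, 3: None, 4: None, 5: None}


# ---------------------------------------------------------------------------
# inventory


@dataclass(frozen=True)
class InventoryRecord:
    name: str
    family: str
    n_carbons: int
    ring_default: RingForm
    enantiomer_default: Enantiomer
    anomeric_position: int
    build: Callable[[Anomer, RingForm, bool], str]  # (anomer, ring, mirror) -> SMILES
    synonym_of: str | None = None


def _aldo_builder(n, senses, deoxy=frozenset(), amino=frozenset(), branches=None):
    def build(anomer: Anomer, ring: RingForm, mirror: bool) -> str:
        size = 6 if ring is RingForm.PYRANOSE else 5
        if n - 1 < size - 1:  # ring cannot exceed the chain (tetroses are furanose-only)
            size = 5
        return _aldose_smiles(n, size, senses, anomer, mirror,
                              deoxy=frozenset(deoxy), amino=frozenset(amino),
                              branches=branches)
    return build


def _keto_builder(n, senses):
    def build(anomer: Anomer, ring: RingForm, mirror: bool) -> str:
        size = 6 if ring is RingForm.PYRANOSE else 5
        return _ketose_smiles(n, size, senses, anomer, mirror)
    return build


def _fixed_builder(fn, **kw):
    def build(anomer: Anomer, ring: RingForm, mirror: bool) -> str:
        return fn(anomer, mirror, **kw)
    return build


def _make_inventory() -> dict[str, InventoryRecord]:
    recs: list[InventoryRecord] = []
    P, F = RingForm.PYRANOSE, RingForm.FURANOSE
    D, L = Enantiomer.D, Enantiomer.L

    def add(name, family, n, ring, enant, anompos, build, synonym_of=None):
        recs.append(InventoryRecord(name, family, n, ring, enant, anompos,
                                    build, synonym_of))

    for nm, s in _HEXOSES.items():
        add(nm, "aldohexose", 6, P, L if nm == "Ido" else D, 1, _aldo_builder(6, s))
    for nm, s in _PENTOSES.items():
        add(nm, "aldopentose", 5, P, L if nm == "Ara" else D, 1, _aldo_builder(5, s))
    for nm, s in _TETROSES.items():
        add(nm, "aldotetrose", 4, F, D, 1, _aldo_builder(4, s))
    for nm, s in _KETOHEXOSES.items():
        add(nm, "ketohexose", 6, F, L if nm == "Sor" else D, 2, _keto_builder(6, s))
    for nm, s in _KETOPENTOSES.items():
        add(nm, "ketopentose", 5, F, D, 2, _keto_builder(5, s))
    # sedoheptulose: D-altro-hept-2-ulose
    add("Sed", "ketoheptose", 7, F, D, 2,
        _keto_builder(7, {3: "L", 4: "R", 5: "R", 6: "R"}))

    # named deoxy sugars (configuration of the parent aldohexose, minus centers)
    deox = {
        # name: (parent senses, deoxy set, default enantiomer)
        "Fuc": (_HEXOSES["Gal"], {6}, L),
        "Rha": (_HEXOSES["Man"], {6}, L),
        "Qui": (_HEXOSES["Glc"], {6}, D),
        "Oli": (_HEXOSES["Glc"], {2, 6}, D),   # 2,6-dideoxy-arabino
        "Tyv": (_HEXOSES["Man"], {3, 6}, D),   # 3,6-dideoxy-arabino
        "Abe": (_HEXOSES["Gal"], {3, 6}, D),   # 3,6-dideoxy-xylo
        "Par": (_HEXOSES["Glc"], {3, 6}, D),   # 3,6-dideoxy-ribo
        "Dig": (_HEXOSES["All"], {2, 6}, D),   # 2,6-dideoxy-ribo
        "Col": (_HEXOSES["Gal"], {3, 6}, L),   # 3,6-dideoxy-L-xylo
        "Asc": (_HEXOSES["Man"], {3, 6}, L),   # 3,6-dideoxy-L-arabino
    }
    for nm, (s, dx, en) in deox.items():
        add(nm, "deoxyhexose", 6, P, en, 1, _aldo_builder(6, s, deoxy=dx))

    # amino-deoxy sugars
    add("Per", "aminodeoxyhexose", 6, P, D, 1,
        _aldo_builder(6, _HEXOSES["Man"], deoxy={6}, amino={4}))   # perosamine
    add("Vio", "aminodeoxyhexose", 6, P, D, 1,
        _aldo_builder(6, _HEXOSES["Glc"], deoxy={6}, amino={4}))   # viosamine
    add("Bac", "aminodeoxyhexose", 6, P, D, 1,
        _aldo_builder(6, _HEXOSES["Glc"], deoxy={6}, amino={2, 4}))  # bacillosamine
    # muramic acid: 2-amino-2-deoxy-Glc with a 3-O-lactyl ether
    add("Mur", "aminosugar", 6, P, D, 1,
        _aldo_builder(6, _HEXOSES["Glc"], amino={2},
                      branches={3: "OC(C)C(O)=O"}))

    # named O-methyl deoxy sugars
    add("Aco", "methyldeoxyhexose", 6, P, L, 1,                    # acofriose
        _aldo_builder(6, _HEXOSES["Man"], deoxy={6}, branches={3: "OC"}))
    add("Cym", "methyldeoxyhexose", 6, P, D, 1,                    # cymarose
        _aldo_builder(6, _HEXOSES["All"], deoxy={2, 6}, branches={3: "OC"}))
    add("Ole", "methyldeoxyhexose", 6, P, L, 1,                    # oleandrose
        _aldo_builder(6, _HEXOSES["Glc"], deoxy={2, 6}, branches={3: "OC"}))

    # heptoses; the C6 glycero center distinguishes the two LPS heptoses
    add("LDManHep", "heptose", 7, P, D, 1,
        _aldo_builder(7, {**_HEXOSES["Man"], 6: "L"}))
    add("DDManHep", "heptose", 7, P, D, 1,
        _aldo_builder(7, {**_HEXOSES["Man"], 6: "R"}))
    add("Hep", "heptose", 7, P, Enantiomer.UNSPECIFIED, 1,
        _aldo_builder(7, {2: None, 3: None, 4: None, 5: None, 6: None}))

    # ulosonic / sialic acids
    add("Neu", "ulosonic", 9, P, D, 2, _fixed_builder(_nonulosonic_smiles))
    add("Kdn", "ulosonic", 9, P, D, 2, _fixed_builder(_nonulosonic_smiles, x5="O"))
    add("Sia", "ulosonic", 9, P, D, 2,
        _fixed_builder(_nonulosonic_smiles, x5="CC(=O)N"))  # N-acetylneuraminic graph
    add("Leg", "ulosonic", 9, P, D, 2,
        _fixed_builder(_nonulosonic_smiles, x7="N", deoxy9=True))
    add("Pse", "ulosonic", 9, P, L, 2,
        _fixed_builder(_nonulosonic_smiles, x7="N", deoxy9=True,
                       flips=frozenset({2, 4, 5, 6, 7, 8})))
    add("Aci", "ulosonic", 9, P, L, 2,
        _fixed_builder(_nonulosonic_smiles, x7="N", deoxy9=True,
                       flips=frozenset({2, 4, 5, 6, 7})))
    add("Kdo", "ulosonic", 8, P, D, 2, _fixed_builder(_kdo_like_smiles))
    add("Ko", "ulosonic", 8, P, D, 2, _fixed_builder(_kdo_like_smiles, c3_oh=True))
    add("Dha", "ulosonic", 7, P, D, 2, _fixed_builder(_dha_smiles))

    add("Api", "branched", 5, F, D, 1, _fixed_builder(_apiose_smiles))

    # generic (wildcard-stereocenter) templates
    add("Hex", "generic", 6, P, Enantiomer.UNSPECIFIED, 1, _aldo_builder(6, _BLANK6))
    add("Pen", "generic", 5, P, Enantiomer.UNSPECIFIED, 1,
        _aldo_builder(5, {2: None, 3: None, 4: None}))
    add("dHex", "generic", 6, P, Enantiomer.UNSPECIFIED, 1,
        _aldo_builder(6, _BLANK6, deoxy={6}))
    add("ddHex", "generic", 6, P, Enantiomer.UNSPECIFIED, 1,
        _aldo_builder(6, _BLANK6, deoxy={2, 6}))

    # synonyms: ambiguous descriptor names mapping onto one canonical graph
    by_name = {r.name: r for r in recs}
    for syn, canon in [("AraHex", "Glc"), ("LyxHex", "Gal"),
                       ("RibHex", "All"), ("XylHex", "Gul"), ("Pent", "Pen")]:
        c = by_name[canon]
        recs.append(InventoryRecord(syn, "synonym", c.n_carbons, c.ring_default,
                                    c.enantiomer_default, c.anomeric_position,
                                    c.build, synonym_of=canon))
    return {r.name: r for r in recs}


INVENTORY: dict[str, InventoryRecord] = _make_inventory()
_NAMES_BY_LENGTH = sorted(INVENTORY, key=len, reverse=True)


def inventory() -> list[InventoryRecord]:
    """All inventory records (synonyms included), stable order."""
    return list(INVENTORY.values())


def inventory_names() -> list[str]:
    return list(INVENTORY)


def write_inventory_tsv(path) -> None:
    """Dump the versioned inventory table: name, class, ring default,
    enantiomer default, atom-graph serialization (template SMILES)."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["name", "class", "ring_default", "enantiomer_default",
                    "synonym_of", "template_smiles"])
        for r in inventory():
            smi = r.build(Anomer.ALPHA, r.ring_default,
                          r.enantiomer_default is Enantiomer.L)
            w.writerow([r.name, r.family, r.ring_default.name.lower(),
                        r.enantiomer_default.value, r.synonym_of or "", smi])


# ---------------------------------------------------------------------------
# templates


class MonomerTemplate:
    """A deep, independently mutable monosaccharide molecule with its
    carbon-position index map and attachment-site registry."""

    def __init__(self, base_name: str, enantiomer: Enantiomer, anomer: Anomer,
                 ring_form: RingForm, mol: Chem.RWMol, anomeric_position: int,
                 n_carbons: int):
        self.base_name = base_name
        self.enantiomer = enantiomer
        self.anomer = anomer
        self.ring_form = ring_form
        self.mol = mol
        self.anomeric_position = anomeric_position
        self.n_carbons = n_carbons
        self.used_positions: set[int] = set()

    # -- position / attachment registry ------------------------------------

    def carbon_idx(self, position: int) -> int | None:
        for atom in self.mol.GetAtoms():
            if atom.GetAtomicNum() == 6 and atom.GetAtomMapNum() == position:
                return atom.GetIdx()
        return None

    def attachment(self, position: int) -> tuple[int, Site] | None:
        """Default attachable atom at a carbon position: its hydroxyl
        oxygen, else its amino nitrogen, else the carbon itself."""
        cidx = self.carbon_idx(position)
        if cidx is None:
            return None
        carbon = self.mol.GetAtomWithIdx(cidx)
        best: tuple[int, Site] | None = None
        for nb in carbon.GetNeighbors():
            bond = self.mol.GetBondBetweenAtoms(cidx, nb.GetIdx())
            if bond.GetBondType() != Chem.BondType.SINGLE:
                continue
            if nb.GetAtomicNum() == 8 and nb.GetTotalNumHs() >= 1 and not nb.IsInRing():
                return nb.GetIdx(), Site.O
            if nb.GetAtomicNum() == 7 and nb.GetTotalNumHs() >= 1 and best is None:
                best = (nb.GetIdx(), Site.N)
        return best if best is not None else (cidx, Site.C)

    def hydroxyl_at(self, position: int) -> int | None:
        at = self.attachment(position)
        if at is not None and at[1] is Site.O:
            return at[0]
        return None

    def anomeric_hydroxyl(self) -> int | None:
        return self.hydroxyl_at(self.anomeric_position)

    def free_hydroxyl_positions(self) -> list[int]:
        """Carbon positions (excluding the anomeric one) that still carry an
        unconsumed hydroxyl — the chemically free slots for modifications
        and child linkages."""
        out = []
        for pos in range(1, self.n_carbons + 1):
            if pos == self.anomeric_position or pos in self.used_positions:
                continue
            if self.hydroxyl_at(pos) is not None:
                out.append(pos)
        return out

    # -- chemistry helpers --------------------------------------------------

    def formula(self) -> str:
        from rdkit.Chem import rdMolDescriptors

        return rdMolDescriptors.CalcMolFormula(Chem.Mol(self.mol))

    def to_smiles(self, strip_maps: bool = True) -> str:
        mol = Chem.Mol(self.mol)
        if strip_maps:
            for a in mol.GetAtoms():
                a.SetAtomMapNum(0)
        return Chem.MolToSmiles(mol)

    def copy(self) -> "MonomerTemplate":
        t = MonomerTemplate(self.base_name, self.enantiomer, self.anomer,
                            self.ring_form, Chem.RWMol(self.mol),
                            self.anomeric_position, self.n_carbons)
        t.used_positions = set(self.used_positions)
        return t


def lookup_template(
    base_name: str,
    anomer: Anomer = Anomer.UNSPECIFIED,
    ring_form: RingForm = RingForm.UNSPECIFIED,
    enantiomer: Enantiomer = Enantiomer.UNSPECIFIED,
) -> MonomerTemplate:
    """Build a fresh, independently mutable template for a base name with
    the requested anomeric configuration, ring form, and enantiomer."""

    rec = INVENTORY.get(base_name)
    if rec is None:
        raise UnknownMonomerError(f"unknown monosaccharide {base_name!r}")
    ring = rec.ring_default if ring_form is RingForm.UNSPECIFIED else ring_form
    enant = rec.enantiomer_default if enantiomer is Enantiomer.UNSPECIFIED else enantiomer
    mirror = enant is Enantiomer.L
    smiles = rec.build(anomer, ring, mirror)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:  # pragma: no cover - template writer defect
        raise UnknownMonomerError(f"template for {base_name!r} failed to build")
    return MonomerTemplate(rec.synonym_of or base_name, enant, anomer, ring,
                           Chem.RWMol(mol), rec.anomeric_position, rec.n_carbons)


# ---------------------------------------------------------------------------
# compound-token splitting


_ENANT_RE = re.compile(r"([LD])-")
_DEOXY_PREFIX_RE = re.compile(r"(\d)d(?=(?:\dd)*[A-Z])")
_POSITION_RE = re.compile(r"(\d)")


def split_monomer_token(token: str):
    """Split a compound monomer token such as ``ManNAc4S`` or ``6dTal`` into
    its base name plus an ordered modification list.

    Returns ``(base_name, mods, ring_form, enantiomer)``.  Position-less
    tokens keep ``position=None`` (the DEFAULT sentinel) for later
    resolution.  Explicitly duplicated positions (Man2S2P) raise
    :class:`DuplicatePositionError` here.
    """

    from .modifications import FRAGMENTS, fragment_tokens_by_length

    s = token
    enant = Enantiomer.UNSPECIFIED
    m = _ENANT_RE.match(s)
    if m:
        enant = Enantiomer(m.group(1))
        s = s[m.end():]

    mods: list[ModificationSpec] = []
    while (m := _DEOXY_PREFIX_RE.match(s)) is not None:
        frag = FRAGMENTS["d"]
        mods.append(ModificationSpec("d", int(m.group(1)), frag.site_class, frag.action))
        s = s[2:]

    base = None
    for nm in _NAMES_BY_LENGTH:
        if s.startswith(nm):
            base = nm
            break
    if base is None:
        raise UnknownMonomerError(f"no known monosaccharide in token {token!r}")
    s = s[len(base):]

    ring = RingForm.UNSPECIFIED
    if s[:1] == "p":
        ring, s = RingForm.PYRANOSE, s[1:]
    elif s[:1] == "f":
        ring, s = RingForm.FURANOSE, s[1:]

    if s.startswith("-"):
        raise UnsupportedFeatureError(
            f"open-chain/reduced suffix {s!r} in {token!r} is not supported")

    while s:
        pos: int | None = None
        m = _POSITION_RE.match(s)
        if m:
            pos = int(m.group(1))
            if pos < 1:
                raise UnknownModificationError(
                    f"invalid modification position in {token!r}")
            s = s[m.end():]
        tok = None
        for cand in fragment_tokens_by_length():
            if s.startswith(cand):
                tok = cand
                break
        if tok is None:
            raise UnknownModificationError(
                f"unknown modification {s!r} in token {token!r}")
        frag = FRAGMENTS[tok]
        mods.append(ModificationSpec(tok, pos, frag.site_class, frag.action))
        s = s[len(tok):]

    explicit = [m.position for m in mods if m.position is not None]
    dup = {p for p in explicit if explicit.count(p) > 1}
    if dup:
        raise DuplicatePositionError(
            f"two modifications target carbon {sorted(dup)[0]} in {token!r}")
    return base, mods, ring, enant
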