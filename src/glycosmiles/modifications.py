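"""Modification engine: per-carbon surgery on monomer templates.

A modification token edits the template in one of four ways:

* ATTACH  — the fragment bonds to the existing hydroxyl O (or amino N) at
  the position: sulfates, phosphates, methyl/acetyl esters, glycolyl.
* REPLACE — the hydroxyl oxygen is swapped for a nitrogen-containing
  fragment: the amino-type tokens N, NAc, NS, NMe.  On a base that already
  carries an amine at that position (Mur, Neu) only the acyl/sulfo part is
  attached to the nitrogen, so MurNAc and Neu5Ac behave as expected.
* DELETE  — deoxygenation (the ``Xd`` tokens): the hydroxyl O is removed
  and the carbon re-saturated.
* OXIDIZE — the ``A`` uronate token: the terminal CH2OH becomes COOH, the
  single sanctioned multi-atom edit.

Splices follow the placeholder-atom round trip: the displaced atom is
replaced by a sentinel element that cannot occur in any sugar or fragment
(transfermium symbols), the molecule is written to SMILES, the sentinel is
substituted by the fragment text, and the result is re-parsed and
re-validated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

from rdkit import Chem

from .errors import (
    DuplicatePositionError,
    InvalidChemistryError,
    NoDefaultPositionError,
    UndetachableError,
    UnknownModificationError,
)
from .glycan_ast import ModAction, ModificationSpec, Site

if TYPE_CHECKING:  # pragma: no cover
    from .monomers import MonomerTemplate

__all__ = [
    "Fragment",
    "PlaceholderSmiles",
    "FRAGMENTS",
    "fragment_tokens_by_length",
    "resolve_default_position",
    "apply_modification",
    "apply_modification_chain",
    "write_fragment_tsv",
]

# element symbols guaranteed absent from every template and fragment; one
# distinct symbol per simultaneously open slot
SENTINELS = ("Es", "Fm", "Md", "No", "Lr", "Rf", "Db", "Sg", "Bh", "Hs")


@dataclass(frozen=True)
class Fragment:
    """One modification fragment.  ``smiles_body`` has exactly one open
    valence at its first atom (capping it with H gives a valid molecule);
    it is ``None`` for the non-splice actions (d, A)."""

    token: str
    smiles_body: str | None
    site_class: Site
    action: ModAction
    default_position: int | None = None      # fixed standard position, if any
    sialic_default: int | None = None        # standard position on sialic bases


FRAGMENTS: dict[str, Fragment] = {
    f.token: f
    for f in [
        Fragment("S", "S(=O)(=O)O", Site.O, ModAction.ATTACH),
        Fragment("P", "P(=O)(O)O", Site.O, ModAction.ATTACH),
        Fragment("Me", "C", Site.O, ModAction.ATTACH),
        Fragment("Et", "CC", Site.O, ModAction.ATTACH),
        Fragment("Ac", "C(C)=O", Site.O, ModAction.ATTACH, sialic_default=5),
        Fragment("Gc", "C(=O)CO", Site.O, ModAction.ATTACH, sialic_default=5),
        Fragment("Fo", "C=O", Site.O, ModAction.ATTACH),
        Fragment("N", "N", Site.C, ModAction.REPLACE, default_position=2),
        Fragment("NAc", "NC(C)=O", Site.C, ModAction.REPLACE, default_position=2),
        Fragment("NS", "NS(=O)(=O)O", Site.C, ModAction.REPLACE, default_position=2),
        Fragment("NMe", "NC", Site.C, ModAction.REPLACE, default_position=2),
        Fragment("A", None, Site.C, ModAction.OXIDIZE),
        Fragment("d", None, Site.O, ModAction.DELETE),
    ]
}

_TOKENS_BY_LENGTH = sorted(FRAGMENTS, key=len, reverse=True)


def fragment_tokens_by_length() -> list[str]:
    """Fragment tokens, longest first, for greedy token matching."""
    return list(_TOKENS_BY_LENGTH)


def write_fragment_tsv(path) -> None:
    """Dump the versioned fragment table."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["token", "fragment_smiles", "site_class", "action",
                    "default_position", "sialic_default"])
        for f in FRAGMENTS.values():
            w.writerow([f.token, f.smiles_body or "", f.site_class.value,
                        f.action.value, f.default_position or "",
                        f.sialic_default or ""])


@dataclass
class PlaceholderSmiles:
    """A SMILES text containing sentinel element symbols that mark open
    attachment slots; ``slot_map`` maps each sentinel symbol to its
    semantic slot (kind, carbon position)."""

    text: str
    slot_map: dict[str, tuple[str, int]]


# ---------------------------------------------------------------------------


def resolve_default_position(mod: ModificationSpec, base_name: str) -> ModificationSpec:
    """Fill a DEFAULT (dropped-digit) position from the per-token standard
    position table: NAc/N/NS -> 2; Ac/Gc on sialic acids -> 5; A -> the
    terminal exocyclic carbon."""

    if mod.position is not None:
        return mod
    frag = FRAGMENTS.get(mod.token)
    if frag is None:
        raise UnknownModificationError(f"unknown modification {mod.token!r}")

    from .monomers import INVENTORY  # deferred: avoids an import cycle

    rec = INVENTORY.get(base_name)
    pos: int | None = None
    if frag.sialic_default is not None and rec is not None and rec.family == "ulosonic":
        pos = frag.sialic_default
    elif frag.default_position is not None:
        pos = frag.default_position
    elif frag.action is ModAction.OXIDIZE and rec is not None:
        pos = rec.n_carbons
    if pos is None:
        raise NoDefaultPositionError(
            f"modification {mod.token!r} has no standard position on {base_name}")
    return ModificationSpec(mod.token, pos, mod.site, mod.action)


def _fresh_sentinel(mol: Chem.Mol) -> str:
    present = {a.GetSymbol() for a in mol.GetAtoms()}
    for sym in SENTINELS:
        if sym not in present:
            return sym
    raise InvalidChemistryError("sentinel pool exhausted")  # pragma: no cover


def _sentinel_atom(sym: str) -> Chem.Atom:
    atom = Chem.Atom(sym)
    atom.SetNoImplicit(True)
    return atom


def _rooted_smiles_with_sentinel(mol: Chem.RWMol, sym: str) -> str:
    """Write the molecule so the sentinel is never the first atom (its
    substitute text must bond backwards to the preceding atom)."""
    Chem.SanitizeMol(mol)
    sent = next(a for a in mol.GetAtoms() if a.GetSymbol() == sym)
    root = sent.GetNeighbors()[0].GetIdx()
    txt = Chem.MolToSmiles(mol, rootedAtAtom=root)
    if txt.count(f"[{sym}]") != 1:  # pragma: no cover - sentinel bookkeeping defect
        raise InvalidChemistryError("sentinel not unique in placeholder SMILES")
    return txt


def splice(template: "MonomerTemplate", sym: str, body: str) -> None:
    """Substitute ``body`` for the sentinel ``sym`` on the SMILES text,
    then re-parse and re-validate (the Step-2 round trip)."""
    txt = _rooted_smiles_with_sentinel(template.mol, sym)
    new = Chem.MolFromSmiles(txt.replace(f"[{sym}]", body))
    if new is None:
        raise InvalidChemistryError(
            f"splicing fragment {body!r} produced an invalid molecule")
    template.mol = Chem.RWMol(new)


# ---------------------------------------------------------------------------


def apply_modification(template: "MonomerTemplate", mod: ModificationSpec) -> "MonomerTemplate":
    """Apply one modification in place; returns the template for chaining."""

    mod = resolve_default_position(mod, template.base_name)
    pos = mod.position
    assert pos is not None
    if pos in template.used_positions:
        raise DuplicatePositionError(
            f"carbon {pos} of {template.base_name} already carries a modification")
    cidx = template.carbon_idx(pos)
    if cidx is None:
        raise UndetachableError(
            f"{template.base_name} has no carbon {pos}")

    mol = template.mol
    frag = FRAGMENTS[mod.token]

    if mod.action is ModAction.DELETE:
        if pos == template.anomeric_position:
            raise UndetachableError(
                "cannot deoxygenate the anomeric position")
        oidx = template.hydroxyl_at(pos)
        if oidx is None:
            raise UndetachableError(
                f"{template.base_name} has no hydroxy group bound to carbon {pos}")
        mol.RemoveAtom(oidx)
        carbon = mol.GetAtomWithIdx(template.carbon_idx(pos))
        carbon.SetNumExplicitHs(carbon.GetNumExplicitHs() + 1)
        carbon.SetChiralTag(Chem.ChiralType.CHI_UNSPECIFIED)
        Chem.SanitizeMol(mol)

    elif mod.action is ModAction.OXIDIZE:
        carbon = mol.GetAtomWithIdx(cidx)
        if carbon.GetTotalNumHs() < 2 or template.hydroxyl_at(pos) is None:
            raise UndetachableError(
                f"carbon {pos} of {template.base_name} is not a terminal CH2OH")
        carbon.SetNumExplicitHs(carbon.GetTotalNumHs() - 2)
        oidx = mol.AddAtom(Chem.Atom(8))
        mol.AddBond(cidx, oidx, Chem.BondType.DOUBLE)
        Chem.SanitizeMol(mol)

    elif mod.action is ModAction.ATTACH:
        att = template.attachment(pos)
        if att is None or att[1] is Site.C:
            raise UndetachableError(
                f"carbon {pos} of {template.base_name} has no attachable "
                f"heteroatom for {mod.token!r}")
        het_idx, _site = att
        sym = _fresh_sentinel(mol)
        sidx = mol.AddAtom(_sentinel_atom(sym))
        mol.AddBond(het_idx, sidx, Chem.BondType.SINGLE)
        splice(template, sym, frag.smiles_body)

    elif mod.action is ModAction.REPLACE:
        oidx = template.hydroxyl_at(pos)
        if oidx is not None:
            sym = _fresh_sentinel(mol)
            mol.ReplaceAtom(oidx, _sentinel_atom(sym))
            splice(template, sym, frag.smiles_body)
        else:
            att = template.attachment(pos)
            if att is None or att[1] is not Site.N:
                raise UndetachableError(
                    f"carbon {pos} of {template.base_name} has neither a "
                    f"hydroxyl nor an amine for {mod.token!r}")
            acyl = frag.smiles_body[1:]  # strip the leading N: acylate in place
            if not acyl:
                raise UndetachableError(
                    f"carbon {pos} of {template.base_name} already carries an amine")
            sym = _fresh_sentinel(mol)
            sidx = mol.AddAtom(_sentinel_atom(sym))
            mol.AddBond(att[0], sidx, Chem.BondType.SINGLE)
            splice(template, sym, acyl)

    else:  # pragma: no cover
        raise UnknownModificationError(f"unhandled action {mod.action}")

    if mod.action is not ModAction.DELETE:
        # a deleted hydroxyl leaves nothing to collide with; later access to
        # the bare carbon fails with the attachment-atom checks instead
        template.used_positions.add(pos)
    return template


def apply_modification_chain(template: "MonomerTemplate",
                             mods: list[ModificationSpec]) -> "MonomerTemplate":
    """Apply modifications left to right, as written in the token."""
    for mod in mods:
        apply_modification(template, mod)
    return template
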