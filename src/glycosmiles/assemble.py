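"""Assembler: resolve a glycan AST into one SMILES string.

Recursion runs leaves-first.  For every node the monosaccharide template is
instantiated with the anomeric configuration its linkage states, all its
modifications are applied, and each already-assembled child is spliced in:
the parent's hydroxyl oxygen at the stated position is replaced by a
sentinel atom, the parent is written to SMILES, and the sentinel is
substituted by the child's SMILES written starting at its anomeric oxygen —
so the child contributes the bridging glycosidic oxygen and one water is
lost per linkage.  The root keeps its free anomeric hydroxyl (the reducing
end).
"""

from __future__ import annotations

from dataclasses import dataclass

from rdkit import Chem

from .errors import (
    EmptyInputError,
    GlycanError,
    InvalidChemistryError,
    LinkageError,
    NoAttachmentAtomError,
    OccupiedPositionError,
)
from .glycan_ast import GlycanNode, Site
from .lexer import tokenize
from .modifications import (
    PlaceholderSmiles,
    _fresh_sentinel,
    _rooted_smiles_with_sentinel,
    _sentinel_atom,
    apply_modification_chain,
)
from .monomers import MonomerTemplate, lookup_template
from .parser import parse

__all__ = ["ConversionReport", "open_attachment", "assemble", "convert",
           "convert_many"]


def _ring_labels(text: str) -> set[int]:
    """Ring-closure labels used in a SMILES text (digits and %nn pairs
    outside of atom brackets)."""
    labels: set[int] = set()
    depth = 0
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "[":
            depth += 1
        elif ch == "]":
            depth -= 1
        elif depth == 0:
            if ch == "%":
                labels.add(int(text[i + 1:i + 3]))
                i += 3
                continue
            if ch.isdigit():
                labels.add(int(ch))
        i += 1
    return labels


def _renumber_ring_labels(text: str, taken: set[int]) -> str:
    """Remap every ring-closure label of ``text`` onto labels not in
    ``taken``.  Needed before textual splicing: a child's ring digits must
    not pair up with ring digits still open in the parent."""
    mapping: dict[int, str] = {}
    free = (n for n in range(1, 100) if n not in taken)

    def subst(old: int) -> str:
        if old not in mapping:
            n = next(free)
            mapping[old] = str(n) if n <= 9 else f"%{n:02d}"
        return mapping[old]

    out: list[str] = []
    depth = 0
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "[":
            depth += 1
        elif ch == "]":
            depth -= 1
        elif depth == 0:
            if ch == "%":
                out.append(subst(int(text[i + 1:i + 3])))
                i += 3
                continue
            if ch.isdigit():
                out.append(subst(int(ch)))
                i += 1
                continue
        out.append(ch)
        i += 1
    return "".join(out)


@dataclass(frozen=True)
class ConversionReport:
    """Per-input outcome: the SMILES string on success, otherwise an empty
    string plus the structured error code."""

    input: str
    smiles: str
    status: str
    message: str = ""

    @property
    def ok(self) -> bool:
        return self.status == "OK"


def open_attachment(template: MonomerTemplate, position: int,
                    site: Site = Site.O) -> PlaceholderSmiles:
    """Open a child-linkage slot at a carbon position of the template.

    For O sites the parent's hydroxyl oxygen is replaced by the sentinel
    (the child brings the bridging oxygen); for N sites the sentinel bonds
    to the amine; for C sites it replaces one hydrogen.  The template is
    mutated: the position is marked consumed and the sentinel is part of
    its molecule until the caller splices the child in.
    """

    if position in template.used_positions:
        raise OccupiedPositionError(
            f"carbon {position} of {template.base_name} is already occupied")
    cidx = template.carbon_idx(position)
    if cidx is None:
        raise NoAttachmentAtomError(
            f"{template.base_name} has no carbon {position}")
    mol = template.mol
    sym = _fresh_sentinel(mol)

    if site is Site.O:
        oidx = template.hydroxyl_at(position)
        if oidx is None:
            raise NoAttachmentAtomError(
                f"carbon {position} of {template.base_name} has no hydroxyl "
                f"to link through")
        mol.ReplaceAtom(oidx, _sentinel_atom(sym))
    elif site is Site.N:
        att = template.attachment(position)
        if att is None or att[1] is not Site.N:
            raise NoAttachmentAtomError(
                f"carbon {position} of {template.base_name} has no amine")
        sidx = mol.AddAtom(_sentinel_atom(sym))
        mol.AddBond(att[0], sidx, Chem.BondType.SINGLE)
    else:  # C site: replace one hydrogen on the carbon itself
        carbon = mol.GetAtomWithIdx(cidx)
        if carbon.GetTotalNumHs() < 1:
            raise NoAttachmentAtomError(
                f"carbon {position} of {template.base_name} has no hydrogen "
                f"to substitute")
        carbon.SetNumExplicitHs(carbon.GetTotalNumHs() - 1)
        sidx = mol.AddAtom(_sentinel_atom(sym))
        mol.AddBond(cidx, sidx, Chem.BondType.SINGLE)

    template.used_positions.add(position)
    text = _rooted_smiles_with_sentinel(mol, sym)
    return PlaceholderSmiles(text=text, slot_map={sym: ("child", position)})


def _node_template(node: GlycanNode) -> MonomerTemplate:
    template = lookup_template(node.base_name, anomer=node.anomer,
                               ring_form=node.ring_form,
                               enantiomer=node.enantiomer)
    apply_modification_chain(template, node.modifications)
    return template


def _child_glycosyl_smiles(template: MonomerTemplate) -> str:
    """The child's SMILES written starting at its anomeric oxygen, maps
    stripped, ready to substitute for a parent sentinel."""
    oidx = template.anomeric_hydroxyl()
    if oidx is None:
        raise NoAttachmentAtomError(
            f"{template.base_name} has no free anomeric hydroxyl to form a "
            f"glycosidic bond")
    mol = Chem.RWMol(template.mol)
    for a in mol.GetAtoms():
        a.SetAtomMapNum(0)
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol, rootedAtAtom=oidx)


def _assemble_template(node: GlycanNode) -> MonomerTemplate:
    template = _node_template(node)
    for link, child in node.children:
        child_template = _assemble_template(child)
        if link.child_position != child_template.anomeric_position:
            raise LinkageError(
                f"child position {link.child_position} is not the anomeric "
                f"carbon of {child_template.base_name} "
                f"(C{child_template.anomeric_position})")
        child_text = _child_glycosyl_smiles(child_template)
        ps = open_attachment(template, link.parent_position, Site.O)
        (sym, _slot), = ps.slot_map.items()
        child_text = _renumber_ring_labels(child_text, _ring_labels(ps.text))
        new = Chem.MolFromSmiles(ps.text.replace(f"[{sym}]", child_text))
        if new is None:
            raise InvalidChemistryError(
                f"splicing {child_template.base_name} into "
                f"{template.base_name} produced an invalid molecule")
        template.mol = Chem.RWMol(new)
    return template


def assemble(ast: GlycanNode) -> str:
    """Resolve an AST into a single canonical SMILES string."""
    template = _assemble_template(ast)
    mol = Chem.RWMol(template.mol)
    for a in mol.GetAtoms():
        a.SetAtomMapNum(0)
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


def convert(iupac: str) -> ConversionReport:
    """Convert one IUPAC-condensed glycan; never raises.

    On any lexical, grammatical, or chemical failure the report carries an
    empty SMILES string and the structured error code.
    """

    try:
        if not iupac or not iupac.strip():
            raise EmptyInputError("empty input")
        ast = parse(tokenize(iupac))
        smiles = assemble(ast)
        return ConversionReport(input=iupac, smiles=smiles, status="OK")
    except GlycanError as exc:
        return ConversionReport(input=iupac, smiles="", status=exc.code,
                                message=str(exc))
    except Exception as exc:  # pragma: no cover - defensive
        return ConversionReport(input=iupac, smiles="", status="E_INTERNAL",
                                message=f"{type(exc).__name__}: {exc}")


def convert_many(iupacs) -> list[ConversionReport]:
    """Batch conversion: report-and-continue, one report per input."""
    return [convert(s) for s in iupacs]
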