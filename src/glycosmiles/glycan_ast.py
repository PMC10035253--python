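"""Glycan abstract syntax tree.

A glycan in IUPAC-condensed notation is a rooted ordered tree: the root is
the *last* monosaccharide written (the reducing end), and branches in square
brackets hang off the monomer written directly after them.  The parser
produces this tree; the assembler consumes it; :func:`serialize` writes it
back out for round-trip testing.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class Anomer(str, enum.Enum):
    ALPHA = "a"
    BETA = "b"
    UNSPECIFIED = "?"


class RingForm(str, enum.Enum):
    PYRANOSE = "p"
    FURANOSE = "f"
    UNSPECIFIED = "?"


class Enantiomer(str, enum.Enum):
    D = "D"
    L = "L"
    UNSPECIFIED = "?"


class ModAction(str, enum.Enum):
    """How a modification edits the monosaccharide atom graph.

    ATTACH and REPLACE are the two splice flavors (fragment substituted for
    a placeholder atom); DELETE removes a hydroxyl oxygen (the ``Xd`` deoxy
    tokens); OXIDIZE is the single sanctioned multi-atom edit turning the
    terminal CH2OH into COOH (the ``A`` uronate token).
    """

    ATTACH = "attach"    # fragment bonded to the existing O/N at the position
    REPLACE = "replace"  # hydroxyl O swapped for the fragment (amino-type tokens)
    DELETE = "delete"    # deoxygenation
    OXIDIZE = "oxidize"  # CH2OH -> COOH


class Site(str, enum.Enum):
    O = "O"
    N = "N"
    C = "C"


@dataclass(frozen=True)
class ModificationSpec:
    """One modification token: *token* at carbon *position*.

    ``position is None`` encodes the DEFAULT sentinel — the digit was
    dropped in the input (e.g. GalNAc) and must be resolved against the
    per-token default table before application.
    """

    token: str
    position: int | None
    site: Site
    action: ModAction


@dataclass(frozen=True)
class Linkage:
    """A glycosidic bond, e.g. ``(a1-4)``: the child's anomeric carbon
    ``child_position`` bonds through the bridging oxygen to the parent's
    carbon ``parent_position``."""

    child_anomer: Anomer
    child_position: int
    parent_position: int

    def text(self) -> str:
        an = "" if self.child_anomer is Anomer.UNSPECIFIED else self.child_anomer.value
        return f"({an}{self.child_position}-{self.parent_position})"


@dataclass
class GlycanNode:
    """One monosaccharide node of the glycan tree."""

    raw_token: str
    base_name: str
    ring_form: RingForm = RingForm.UNSPECIFIED
    anomer: Anomer = Anomer.UNSPECIFIED
    enantiomer: Enantiomer = Enantiomer.UNSPECIFIED
    modifications: list[ModificationSpec] = field(default_factory=list)
    children: list[tuple[Linkage, "GlycanNode"]] = field(default_factory=list)

    # -- structural equality (ignores the anomer copy on the child node? no:
    #    the anomer is part of the structure; dataclass eq covers everything)

    def node_count(self) -> int:
        return 1 + sum(c.node_count() for _, c in self.children)

    def walk(self):
        """Yield every node, pre-order, root first."""
        yield self
        for _, child in self.children:
            yield from child.walk()


# The AST of a whole glycan is simply its root node.
GlycanAST = GlycanNode


def serialize(ast: GlycanNode) -> str:
    """Write an AST back to IUPAC-condensed text.

    The first child (leftmost in the input) is written inline, every further
    child in square brackets, each followed by its bond; the node's own
    token comes last.  ``parse(serialize(ast))`` is structurally identical
    to ``ast``.
    """

    parts: list[str] = []
    for i, (link, child) in enumerate(ast.children):
        chain = serialize(child) + link.text()
        if i == 0:
            parts.append(chain)
        else:
            parts.append(f"[{chain}]")
    parts.append(ast.raw_token)
    return "".join(parts)
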