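"""Post-conversion utilities: motif counting and DOT export.

Two complementary counting modes, reflecting the two levels a glycan lives
on: monomer-tree motifs (one or more monosaccharides with their linkages)
are counted on the AST, and functional groups (hydroxyls, N-acetyls,
sulfates, ...) are counted on the computed SMILES with SMARTS patterns.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Literal

from rdkit import Chem

from .errors import InvalidPatternError
from .glycan_ast import Anomer, GlycanNode

__all__ = [
    "MotifQuery",
    "count_substructure",
    "count_functional_group",
    "NAMED_PATTERNS",
    "to_dot",
    "parse_dot",
]


@dataclass(frozen=True)
class MotifQuery:
    """Either a monomer-tree motif (payload: a GlycanAST) or an atomic
    pattern (payload: a SMARTS string)."""

    kind: Literal["MONOMER_TREE", "ATOM_PATTERN"]
    payload: object


# common functional groups, by field name
NAMED_PATTERNS: dict[str, str] = {
    "hydroxyl": "[OX2H1]",
    "n_acetyl": "[NX3][CX3](=O)[CH3]",
    "sulfate": "[OX2]S(=O)(=O)[OX2]",
    "phosphate": "[OX2]P(=O)([OX2])[OX2]",
    "carboxyl": "[CX3](=O)[OX2H1]",
    "amine": "[NX3;H2]",
    "methyl_ether": "[OX2]([#6])[CH3]",
}


def _linkage_matches(motif_link, link) -> bool:
    if motif_link.child_position != link.child_position:
        return False
    if motif_link.parent_position != link.parent_position:
        return False
    if motif_link.child_anomer is Anomer.UNSPECIFIED:
        return True  # unspecified anomer in the motif is a wildcard
    return motif_link.child_anomer == link.child_anomer


def _node_matches(motif: GlycanNode, node: GlycanNode) -> bool:
    """Anchored embedding: motif root at this node, descending matching
    linkage labels exactly; extra children of the node are permitted."""
    if motif.base_name != node.base_name:
        return False
    if sorted(m.token + str(m.position) for m in motif.modifications) != \
            sorted(m.token + str(m.position) for m in node.modifications):
        return False
    by_pos = {link.parent_position: (link, child) for link, child in node.children}
    for mlink, mchild in motif.children:
        got = by_pos.get(mlink.parent_position)
        if got is None:
            return False
        link, child = got
        if not _linkage_matches(mlink, link):
            return False
        if not _node_matches(mchild, child):
            return False
    return True


def count_substructure(ast: GlycanNode, motif: MotifQuery | GlycanNode) -> int:
    """Number of nodes of ``ast`` at which the motif tree embeds
    (overlapping embeddings all count)."""
    if isinstance(motif, MotifQuery):
        if motif.kind != "MONOMER_TREE":
            raise InvalidPatternError("count_substructure needs a MONOMER_TREE motif")
        motif = motif.payload  # type: ignore[assignment]
    return sum(1 for node in ast.walk() if _node_matches(motif, node))


def count_functional_group(smiles: str, pattern: MotifQuery | str) -> int:
    """Number of distinct matches of a SMARTS pattern (or a name from
    :data:`NAMED_PATTERNS`) in the molecule behind ``smiles``."""
    if isinstance(pattern, MotifQuery):
        if pattern.kind != "ATOM_PATTERN":
            raise InvalidPatternError("count_functional_group needs an ATOM_PATTERN")
        pattern = pattern.payload  # type: ignore[assignment]
    pattern = NAMED_PATTERNS.get(pattern, pattern)
    query = Chem.MolFromSmarts(pattern)
    if query is None:
        raise InvalidPatternError(f"invalid SMARTS pattern {pattern!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidPatternError(f"invalid SMILES {smiles!r}")
    return len(mol.GetSubstructMatches(query, uniquify=True))


# ---------------------------------------------------------------------------
# DOT export


def _dot_escape(s: str) -> str:
    return s.replace("\\", "\\\\").replace('"', '\\"')


def to_dot(ast: GlycanNode, name: str = "glycan") -> str:
    """Render the glycan tree in the DOT language: one node per monomer
    labeled with its full token, one edge per linkage labeled with the
    bond text."""
    lines = [f"digraph {name} {{"]
    ids: dict[int, str] = {}
    for i, node in enumerate(ast.walk()):
        ids[id(node)] = f"n{i}"
        lines.append(f'  n{i} [label="{_dot_escape(node.raw_token)}"];')
    for node in ast.walk():
        for link, child in node.children:
            label = link.text().strip("()")
            lines.append(
                f'  {ids[id(node)]} -> {ids[id(child)]} [label="{label}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"


_DOT_NODE_RE = re.compile(r'^\s*(\w+)\s*\[label="((?:[^"\\]|\\.)*)"\]\s*;\s*$')
_DOT_EDGE_RE = re.compile(
    r'^\s*(\w+)\s*->\s*(\w+)\s*(?:\[label="((?:[^"\\]|\\.)*)"\])?\s*;\s*$')


def parse_dot(text: str) -> tuple[dict[str, str], list[tuple[str, str, str]]]:
    """Minimal DOT digraph reader: returns (node id -> label, edges as
    (src, dst, label)).  Supports exactly the dialect :func:`to_dot`
    writes; used for round-trip checks."""
    lines = text.strip().splitlines()
    if not lines or not lines[0].startswith("digraph") or lines[-1].strip() != "}":
        raise InvalidPatternError("not a DOT digraph")
    nodes: dict[str, str] = {}
    edges: list[tuple[str, str, str]] = []
    for line in lines[1:-1]:
        if not line.strip():
            continue
        m = _DOT_EDGE_RE.match(line)
        if m:
            edges.append((m.group(1), m.group(2), m.group(3) or ""))
            continue
        m = _DOT_NODE_RE.match(line)
        if m:
            nodes[m.group(1)] = m.group(2)
            continue
        raise InvalidPatternError(f"unparseable DOT line: {line!r}")
    return nodes, edges
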