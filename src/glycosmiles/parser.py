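"""Recursive-descent parser: token stream -> glycan AST.

Grammar (right-rooted; the root monomer is written last):

    glycan  :=  element* MONOMER
    element :=  MONOMER bond            # one link of the running chain
             |  "[" element* MONOMER bond "]"   # a branch, incl. its bond out
    bond    :=  "(" ANOMER? DIGIT "-" DIGIT ")"

Each monomer collects everything written directly before it (the running
chain and any bracketed branches) as its children, in left-to-right input
order.  Inner repeats ``{...}n`` and wildcard bonds ``(?1-?)`` are
recognized and rejected with :class:`UnsupportedFeatureError`.
"""

from __future__ import annotations

from .errors import ParseError, UnsupportedFeatureError
from .glycan_ast import Anomer, GlycanNode, Linkage
from .lexer import Token, TokenKind, tokenize
from .monomers import split_monomer_token

__all__ = ["parse", "parse_string"]


class _Stream:
    def __init__(self, tokens: list[Token]):
        self.tokens = tokens
        self.pos = 0

    def peek(self) -> Token | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> Token:
        tok = self.peek()
        if tok is None:
            raise ParseError("unexpected end of input")
        self.pos += 1
        return tok


def _make_node(tok: Token) -> GlycanNode:
    base, mods, ring, enant = split_monomer_token(tok.text)
    return GlycanNode(raw_token=tok.text, base_name=base, ring_form=ring,
                      enantiomer=enant, modifications=mods)


def _parse_bond(st: _Stream) -> Linkage:
    open_tok = st.next()
    assert open_tok.kind is TokenKind.BOND_OPEN
    inner: list[Token] = []
    while True:
        tok = st.next()
        if tok.kind is TokenKind.BOND_CLOSE:
            break
        inner.append(tok)
    if any(t.kind is TokenKind.QUESTION for t in inner):
        raise UnsupportedFeatureError(
            "wildcard bonds are a structural uncertainty and cannot be "
            "resolved into one molecule", offset=open_tok.offset)

    i = 0
    anomer = Anomer.UNSPECIFIED
    if i < len(inner) and inner[i].kind is TokenKind.ANOMER:
        anomer = Anomer(inner[i].text)
        i += 1

    def read_number() -> int:
        nonlocal i
        digits = ""
        while i < len(inner) and inner[i].kind is TokenKind.DIGIT:
            digits += inner[i].text
            i += 1
        if not digits:
            raise ParseError("malformed bond: expected a carbon position",
                             offset=open_tok.offset)
        return int(digits)

    child_pos = read_number()
    if i >= len(inner) or inner[i].kind is not TokenKind.DASH:
        raise ParseError("malformed bond: expected '-'", offset=open_tok.offset)
    i += 1
    parent_pos = read_number()
    if i != len(inner):
        raise ParseError("malformed bond: trailing characters",
                         offset=open_tok.offset)
    if child_pos not in (1, 2):
        raise ParseError(
            f"child position {child_pos} is not an anomeric carbon (1 or 2)",
            offset=open_tok.offset)
    if not 1 <= parent_pos <= 9:
        raise ParseError(f"parent position {parent_pos} out of range 1-9",
                         offset=open_tok.offset)
    return Linkage(child_anomer=anomer, child_position=child_pos,
                   parent_position=parent_pos)


def _attach(node: GlycanNode, pending: list[tuple[GlycanNode, Linkage]]) -> None:
    seen: set[int] = set()
    for child, link in pending:
        if link.parent_position in seen:
            raise ParseError(
                f"two branches attach at carbon {link.parent_position} of "
                f"{node.raw_token!r}: one cannot attach two substituents to "
                f"the same atom")
        seen.add(link.parent_position)
        node.children.append((link, child))


def _parse_chain(st: _Stream, in_bracket: bool):
    """Parse one strand.  Outside brackets, returns its root node (a bare
    monomer ends the strand).  Inside brackets, returns (root, out-linkage)
    when the closing bracket is reached."""

    pending: list[tuple[GlycanNode, Linkage]] = []
    while True:
        tok = st.peek()
        if tok is None:
            raise ParseError("unexpected end of input")
        if tok.kind in (TokenKind.REPEAT_OPEN, TokenKind.REPEAT_CLOSE):
            raise UnsupportedFeatureError(
                "inner repeats ({...}n) are not supported", offset=tok.offset)
        if tok.kind is TokenKind.BRANCH_OPEN:
            st.next()
            sub, sublink = _parse_chain(st, in_bracket=True)
            close = st.next()
            if close.kind is not TokenKind.BRANCH_CLOSE:
                raise ParseError("expected ']'", offset=close.offset)
            pending.append((sub, sublink))
        elif tok.kind is TokenKind.MONOMER:
            st.next()
            node = _make_node(tok)
            _attach(node, pending)
            pending = []
            nxt = st.peek()
            if nxt is not None and nxt.kind is TokenKind.BOND_OPEN:
                link = _parse_bond(st)
                node.anomer = link.child_anomer
                after = st.peek()
                if in_bracket and after is not None \
                        and after.kind is TokenKind.BRANCH_CLOSE:
                    return node, link
                pending.append((node, link))
            else:
                if in_bracket:
                    raise ParseError(
                        "a bracketed branch must end with its bond to the "
                        "attachment monomer", offset=tok.offset)
                if pending:
                    raise ParseError("dangling branch before end of input",
                                     offset=tok.offset)
                return node
        elif tok.kind is TokenKind.BRANCH_CLOSE:
            raise ParseError("unbalanced ']'", offset=tok.offset)
        else:
            raise ParseError(f"unexpected token {tok.text!r}", offset=tok.offset)


def parse(tokens: list[Token]) -> GlycanNode:
    """Parse a token stream into a GlycanAST; the root is the rightmost
    monomer of the input."""
    st = _Stream(tokens)
    root = _parse_chain(st, in_bracket=False)
    trailing = st.peek()
    if trailing is not None:
        raise ParseError(f"trailing tokens after the root monomer",
                         offset=trailing.offset)
    return root


def parse_string(text: str) -> GlycanNode:
    """Convenience wrapper: tokenize then parse."""
    return parse(tokenize(text))
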