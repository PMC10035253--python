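"""Tokenizer for IUPAC-condensed glycan strings.

The lexer is a small state machine: outside a bond, maximal runs of
letters/digits (plus an optional ``L-``/``D-`` enantiomer prefix) are
MONOMER tokens; inside ``( ... )`` the characters are bond tokens
(anomer letter, digits, dash).  Token texts partition the (trimmed) input
exactly — no gaps, no overlaps — so the parser can report precise offsets.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass

from .errors import LexError

__all__ = ["TokenKind", "Token", "tokenize"]


class TokenKind(enum.Enum):
    MONOMER = "MONOMER"
    MODIFIER = "MODIFIER"  # emitted by monomer-token splitting, not by this scanner
    BOND_OPEN = "BOND_OPEN"
    BOND_CLOSE = "BOND_CLOSE"
    BRANCH_OPEN = "BRANCH_OPEN"
    BRANCH_CLOSE = "BRANCH_CLOSE"
    ANOMER = "ANOMER"
    DIGIT = "DIGIT"
    DASH = "DASH"
    REPEAT_OPEN = "REPEAT_OPEN"
    REPEAT_CLOSE = "REPEAT_CLOSE"
    QUESTION = "QUESTION"


@dataclass(frozen=True)
class Token:
    kind: TokenKind
    text: str
    offset: int


# A monomer token: optional enantiomer prefix, then letters/digits, with an
# optional "-ol"/"-onic" style suffix (recognized so it can be rejected with
# a precise "unsupported" error rather than a lex error).
_MONOMER_RE = re.compile(r"(?:[LD]-)?[A-Za-z0-9]+(?:-(?:ol|onic|aric|uronic))?")

_DASHES = ("-", "–")  # ASCII hyphen and the en-dash used in print


def tokenize(text: str) -> list[Token]:
    """Tokenize one IUPAC-condensed glycan string.

    Leading/trailing whitespace is trimmed; internal whitespace is a
    :class:`LexError` (the notation is whitespace-free).
    """

    s = text.strip()
    if not s:
        raise LexError("empty input", offset=0)

    tokens: list[Token] = []
    i = 0
    in_bond = False
    n = len(s)
    while i < n:
        ch = s[i]
        if ch.isspace():
            raise LexError("internal whitespace is not allowed", offset=i)
        if ch == "(":
            tokens.append(Token(TokenKind.BOND_OPEN, ch, i))
            in_bond = True
            i += 1
        elif ch == ")":
            tokens.append(Token(TokenKind.BOND_CLOSE, ch, i))
            in_bond = False
            i += 1
        elif ch == "[":
            tokens.append(Token(TokenKind.BRANCH_OPEN, ch, i))
            i += 1
        elif ch == "]":
            tokens.append(Token(TokenKind.BRANCH_CLOSE, ch, i))
            i += 1
        elif ch == "{":
            tokens.append(Token(TokenKind.REPEAT_OPEN, ch, i))
            i += 1
        elif ch == "}":
            tokens.append(Token(TokenKind.REPEAT_CLOSE, ch, i))
            i += 1
        elif ch == "?":
            tokens.append(Token(TokenKind.QUESTION, ch, i))
            i += 1
        elif in_bond:
            if ch in ("a", "b"):
                tokens.append(Token(TokenKind.ANOMER, ch, i))
                i += 1
            elif ch.isdigit():
                tokens.append(Token(TokenKind.DIGIT, ch, i))
                i += 1
            elif ch in _DASHES:
                tokens.append(Token(TokenKind.DASH, ch, i))
                i += 1
            elif ch == "/":
                # multi-position bonds like (a1-4/6) are structural
                # uncertainty; lex as QUESTION so the parser rejects them
                # as unsupported rather than unlexable
                tokens.append(Token(TokenKind.QUESTION, ch, i))
                i += 1
            else:
                raise LexError(f"unexpected character {ch!r} inside bond", offset=i)
        else:
            m = _MONOMER_RE.match(s, i)
            if m is None:
                raise LexError(f"unrecognized character {ch!r}", offset=i)
            tokens.append(Token(TokenKind.MONOMER, m.group(0), i))
            i = m.end()
    return tokens
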