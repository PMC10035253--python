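"""Structured error taxonomy.

Every failure mode of the converter maps to one exception class carrying a
stable ``code``.  Batch conversion never lets these escape: :func:`~glycosmiles.assemble.convert`
catches any :class:`GlycanError` and reports the code alongside an empty
SMILES string, so pipelines can distinguish *why* a record failed without
parsing prose messages.
"""

from __future__ import annotations


class GlycanError(Exception):
    """Base class for all glycan-related failures."""

    code = "E_GLYCAN"

    def __init__(self, message: str, offset: int | None = None):
        super().__init__(message)
        self.offset = offset

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        base = super().__str__()
        if self.offset is not None:
            return f"{base} (at offset {self.offset})"
        return base


class LexError(GlycanError):
    """Unrecognized character sequence in the input string."""

    code = "E_LEX"


class ParseError(GlycanError):
    """Token stream violates the glycan grammar (unbalanced brackets,
    malformed bond, trailing tokens, colliding attachment positions)."""

    code = "E_PARSE"


class UnsupportedFeatureError(GlycanError):
    """Syntactically recognizable construct that is out of scope:
    inner repeats ``{...}n``, wildcard bonds ``(?1-?)``, reduced ends."""

    code = "E_UNSUPPORTED"


class UnknownMonomerError(GlycanError):
    """Base monosaccharide name not present in the template inventory."""

    code = "E_UNKNOWN_MONOMER"


class UnknownModificationError(GlycanError):
    """Modification token not present in the fragment inventory."""

    code = "E_UNKNOWN_MODIFICATION"


class DuplicatePositionError(GlycanError):
    """Two modifications (or a modification and a linkage) target the same
    atom, e.g. Man2S2P."""

    code = "E_DUPLICATE_POSITION"


class UndetachableError(GlycanError):
    """The target atom for a modification does not exist, e.g. 2dDig
    (digitoxose has no hydroxyl at carbon 2)."""

    code = "E_UNDETACHABLE"


class NoDefaultPositionError(GlycanError):
    """A position-less modification token has no standard position on the
    given base monosaccharide."""

    code = "E_NO_DEFAULT_POSITION"


class OccupiedPositionError(GlycanError):
    """An attachment slot was requested twice."""

    code = "E_OCCUPIED_POSITION"


class NoAttachmentAtomError(GlycanError):
    """A linkage points at a position with no attachable atom (e.g. through
    a deoxygenated carbon)."""

    code = "E_NO_ATTACHMENT_ATOM"


class LinkageError(GlycanError):
    """Chemically impossible linkage description, e.g. a child position that
    is not the anomeric carbon of the child monosaccharide."""

    code = "E_LINKAGE"


class InvalidChemistryError(GlycanError):
    """Assembled molecule failed valence validation."""

    code = "E_CHEMISTRY"


class EmptyInputError(GlycanError):
    """Empty or whitespace-only input line."""

    code = "E_EMPTY"


class InvalidPatternError(GlycanError):
    """Malformed substructure (SMARTS) pattern."""

    code = "E_PATTERN"
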