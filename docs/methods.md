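# Methods

## The conversion model

A glycan in IUPAC-condensed notation is treated as a sentence in a small
formal language and compiled, in three passes, into SMILES.

**Grammar.** The accepted language is

```
glycan  :=  element* MONOMER
element :=  MONOMER bond  |  "[" element* MONOMER bond "]"
bond    :=  "(" (a|b)? DIGIT "-" DIGIT ")"
```

with the rightmost monomer as the tree root (the reducing end) and each
monomer collecting everything written directly before it — the running
chain and any bracketed branches — as children in left-to-right order.
Brackets may nest arbitrarily. Both the ASCII hyphen and the typographic
en-dash are accepted inside bonds and normalized to `-` on serialization.
Two children on the same parent carbon are rejected at parse time: a carbon
cannot carry two substituents on one oxygen. The first bond position must
be 1 or 2 (an anomeric carbon); the assembler later checks it equals the
anomeric position of the actual child base (so `Neu5Ac(a2-3)` works and
`Man(a2-4)` fails).

Monomer tokens are compound: optional `L-`/`D-` prefix, optional `Xd`
deoxy prefixes, the longest matching base name from the inventory, an
optional `p`/`f` ring suffix, then position+token modification suffixes
(`Neu5Ac`, `Man3S4P`, `GalNAc`). A dropped digit is recorded as a DEFAULT
sentinel and resolved later (NAc/N/NS → 2; Ac/Gc → 5 on sialic bases;
A → the terminal carbon); a token with no standard position is an error,
not a guess.

**Templates.** Each base monosaccharide is an RDKit molecule whose backbone
carbons carry atom-map numbers equal to their IUPAC indices. Templates are
generated, not hand-typed: a sugar is described by family (aldose/ketose,
chain length, ring size) plus its Fischer configuration pattern, and a
skeleton writer emits SMILES in a fixed atom order where each slot has one
constant chirality tag meaning "hydroxyl on the right". Epimers flip single
tags; an L-sugar flips every tag (the full mirror image, which also inverts
what α/β mean geometrically — so α-L-Fuc is the mirror of α-D-Fuc, as it
must be). The constants are calibrated against α-D-glucopyranose
(`OC[C@H]1O[C@H](O)[C@H](O)[C@@H](O)[C@@H]1O`) and β-D-fructofuranose;
the test suite pins these plus the β-anomers of Glc/Man/Gal and checks the
eight aldohexoses are eight distinct stereoisomers of one constitution.

The inventory holds 60 names: aldohexoses, aldopentoses, aldotetroses,
ketoses (default furanose), the named deoxy (Fuc … Asc), amino-deoxy
(Per, Vio, Bac), and O-methyl (Aco, Cym, Ole) sugars, LPS heptoses,
ulosonic/sialic acids (Neu, Kdn, Kdo, Ko, Dha, Leg, Pse, Aci, and Sia as
the N-acetylneuraminic graph), muramic acid, apiose, generic wildcard
templates (Hex, Pen, Hep, dHex, ddHex — stereocenters untagged), and
descriptor-hexose synonyms (AraHex≡Glc, LyxHex≡Gal, RibHex≡All,
XylHex≡Gul, Pent≡Pen) that share the canonical atom graph, so 2dAraHex
and 2dGlc compile to the same SMILES. Synonyms resolve silently: the
converter performs no semantic plausibility checks beyond atom existence.

Stereo caveats, stated plainly: the C6 glycero center of the heptoses, the
apiose quaternary center, and the ring tags of the rare nonulosonates
(Leg, Pse, Aci — derived from the Neu scaffold by descriptor arithmetic)
are best-effort assignments; the muramic-acid lactyl center is left
undefined. None of these affect constitution, valence, or any linkage
chemistry.

**Modifications.** Four edit classes: ATTACH bonds a fragment to the
existing hydroxyl O (or amino N — Neu + 5Ac acylates the amine, giving
Neu5Ac ≡ the Sia template, which a test confirms by InChI); REPLACE swaps
the hydroxyl for an amino-type fragment, or acylates in place when the
base already has an amine there (MurNAc); DELETE removes the hydroxyl and
re-saturates the carbon (refused at the anomeric position, where it would
destroy the hemiacetal); OXIDIZE is the single sanctioned multi-atom edit,
CH2OH → COOH for uronates (GlcA). Splices follow a placeholder round
trip: the displaced atom is replaced by a sentinel element taken from a
pool of transfermium symbols that cannot occur in any sugar or fragment,
the molecule is written to SMILES, the sentinel text is substituted by the
fragment body (whose first atom is its attachment atom), and the result is
re-parsed and sanitized. Swapping an atom for the sentinel in place keeps
every neighbor-order-dependent chirality flag valid; a test verifies CIP
labels away from the edit are untouched, and that splices at distinct
positions commute.

**Assembly.** Recursion is leaves-first. For a linkage `(a1-4)`: the
child's template is instantiated with the stated anomer, its subtree fully
assembled, and its SMILES written starting at its anomeric oxygen; the
parent's C4 hydroxyl oxygen is replaced by a sentinel and the child text
substituted in. The bridging oxygen therefore arrives with the child and
the parent loses its hydroxyl — exactly one water per bond, which makes
the formula of an n-mer hexose chain C(6n)H(10n+2)O(5n+1), an identity the
tests check for n = 1..10. Ring-closure digits in the child text are
renumbered away from any label used in the parent before substitution;
without this, a digit still open in the parent can pair with a child digit
and silently mis-close rings (the regression test asserts every ring in an
assembled glycan is a 5- or 6-membered sugar ring). The final molecule is
emitted as RDKit canonical SMILES; equality of structures is always judged
by InChI/graph, never by string identity.

N-sites (glycosylamines) and C-sites are supported by `open_attachment`
for completeness: N-linkage consumes an amine hydrogen, C-linkage a carbon
hydrogen. Bridging diester phosphates between monomers are not modeled.

## Error taxonomy

Every failure maps to a stable code (`E_LEX`, `E_PARSE`, `E_UNSUPPORTED`,
`E_UNKNOWN_MONOMER`, `E_UNKNOWN_MODIFICATION`, `E_DUPLICATE_POSITION`,
`E_UNDETACHABLE`, `E_NO_DEFAULT_POSITION`, `E_OCCUPIED_POSITION`,
`E_NO_ATTACHMENT_ATOM`, `E_LINKAGE`, `E_CHEMISTRY`, `E_EMPTY`).
`convert()` is total: it never raises, returning an empty SMILES plus the
code, and batch conversion reports-and-continues. Wildcard bonds and inner
repeats are recognized syntax rejected as `E_UNSUPPORTED` — a structural
uncertainty cannot be resolved into one molecule, and enumerating the
alternatives is deliberately out of scope.

## The fuzz generator

`glycosmiles.fuzz` builds random rooted trees top-down. At each node it
samples a base from the pool (15 common aldoses/deoxy sugars by default),
then walks the base's chemically free hydroxyl positions: each gets a
modification with probability 0.2 (from S, P, Me, Ac, NAc, d; amino-type
tokens only at C2), and each remaining free position sprouts a child with
probability 0.3, to depth ≤ 5. Defaults are the corpus conditions used
throughout the tests and the acceptance script; with ~3–4 free positions
per node they give a near-critical branching process whose trees average
~3.5 nodes (max observed ≈ 20). Because sampling respects the attachment
registry and the one-modification-per-atom rule, every emitted string is
convertible by construction — the generator probes the grammar and
assembly machinery, while chemistry errors are exercised by hand-written
cases. What passing fuzz does **not** show: real-world token dialects
(`GalNAc` written without its digit, enantiomer prefixes, furanose
suffixes appear in hand-written tests only), monomer frequencies of
natural glycomes, or unusual chemistry outside the sampled pools.

Randomness: each corpus item derives its own `random.Random` from
`(seed * 1000003 + index) mod 2^31`, so corpora are reproducible and
byte-identical per (seed, index) regardless of generation order.

## Numerical and design choices

* Ring-form defaults are per base (furanose for ketoses, apiose and
  tetroses; pyranose otherwise); an explicit `p`/`f` suffix overrides.
* Default enantiomers follow carbohydrate convention (L for Fuc, Rha, Ara,
  Ido, Sor, Col, Asc, Aco, Ole, Pse, Aci; D otherwise), overridable by a
  `D-`/`L-` prefix.
* An unwritten anomer is *unspecified*, never coerced: the root of a
  glycan gets an untagged hemiacetal carbon (visible in the 2dGlc output).
* Tokenization partitions the trimmed input exactly; internal whitespace
  is a lexical error.
* Deleting a hydroxyl does not mark the position "occupied": later access
  fails with the truthful no-attachment-atom error instead.
* Degenerate inputs: the empty string reports `E_EMPTY`; a single monomer
  converts to its free sugar.

## Limitations

Cyclic and unrooted glycans, inner repeats, wildcard enumeration, open
chain/alditol forms (`-ol`), non-sugar backbone units, bridging phosphate
diesters, and modifications replacing more than one heavy atom (beyond
uronate oxidation) are rejected rather than approximated. The inventory
and fragment tables are deliberately versioned data (`write_inventory_tsv`,
`write_fragment_tsv`) so extending them is additive.
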