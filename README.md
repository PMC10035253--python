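# glycosmiles

Glycans — the branched carbohydrate polymers that decorate proteins, lipids
and cell surfaces — are almost always written in the compact IUPAC-condensed
notation (`Gal(b1-4)GlcNAc`, branches in square brackets, the reducing-end
root written last). That notation is great for people and useless for
cheminformatics: docking, substructure search, molecular dynamics and
molecule-level machine learning all need the atomic structure. `glycosmiles`
is an offline compiler from IUPAC-condensed glycan strings to SMILES, for
glycobiologists and cheminformaticians who need atom-resolved glycans inside
automated pipelines.

## How it works

The converter is a three-step compiler:

1. **Parse.** A lexer and recursive-descent parser turn the string into a
   rooted glycan tree (the AST). The root is the *last* monosaccharide; a
   bracketed branch hangs off the monomer written directly after it, so
   `Man(a1-4)Man(a1-3)[Man(a1-4)Man(a1-4)]Man(a1-4)Man` is a 6-node tree
   whose fork carries chains at carbons 3 and 4.
2. **Modify.** Each node's token is split into a base monosaccharide plus
   modification tokens (`ManNAc4S` → Man + NAc@2 + S@4). The base is
   instantiated from a library of 60 stereochemically annotated pyranose/
   furanose templates in which every backbone carbon is indexed, and each
   modification edits the template at its carbon: sulfates/phosphates/acyls
   attach to the hydroxyl oxygen, amino-type tokens replace it, `Xd` deletes
   it, `A` oxidizes the terminal CH2OH to a carboxylic acid. Splices run
   through a placeholder atom: the displaced atom becomes a sentinel
   element, the molecule is written to SMILES, the sentinel is substituted
   by the fragment text, and the result is re-parsed and valence-checked.
3. **Assemble.** Leaves-first, each child's SMILES (written from its
   anomeric oxygen, with the anomeric α/β tag its linkage states) replaces
   the sentinel standing where the parent's hydroxyl was — one water lost
   per glycosidic bond — until the root yields a single canonical SMILES
   with a free reducing-end hydroxyl.

Inputs the converter cannot represent as one molecule (wildcard bonds
`(?1-?)`, inner repeats `{...}n`, chemically impossible tokens like
`Man2S2P` or `2dDig`) return an **empty string plus a structured error
code** instead of raising, so batch runs never abort.

## Worked example

```python
>>> from glycosmiles import convert
>>> r = convert("Gal(a1-6)ManNAc4S(a1-4)Gal")
>>> r.status
'OK'
>>> r.smiles
'CC(=O)N[C@@H]1[C@@H](O[C@@H]2[C@H](O)[C@@H](O)C(O)O[C@@H]2CO)O[C@H](CO[C@H]2O[C@H](CO)[C@H](O)[C@H](O)[C@H]2O)[C@@H](OS(=O)(=O)O)[C@@H]1O'
```

Three pyranose rings; the acetamide (`CC(=O)N`) sits on the mannose C2, the
sulfate ester (`OS(=O)(=O)O`) on its C4, and the unwritten root anomer
appears as the untagged `C(O)` hemiacetal. Counting confirms the chemistry:

```python
>>> from glycosmiles.glycan_utils import count_functional_group, count_substructure
>>> count_functional_group(r.smiles, "sulfate"), count_functional_group(r.smiles, "hydroxyl")
(1, 10)
>>> from glycosmiles import parse_string
>>> count_substructure(parse_string("Man(a1-4)Man(a1-4)Man(a1-4)Man"),
...                    parse_string("Man(a1-4)Man"))
3
>>> convert("Man2S2P")   # two modifications on one atom is impossible
ConversionReport(input='Man2S2P', smiles='', status='E_DUPLICATE_POSITION',
                 message="two modifications target carbon 2 in 'Man2S2P'")
```

The same API is available from the shell:

```
$ glycosmiles convert "Gal(b1-4)Glc" -o smiles.txt
$ glycosmiles validate -i glycans.txt
$ glycosmiles dot "Gal(a1-6)ManNAc4S(a1-4)Gal"
$ glycosmiles fuzz --seed 7 --n 1000 -o corpus.tsv
```

`convert` writes one SMILES per input line (an empty line where a record
failed, diagnostics with error codes on stderr) and exits non-zero if any
record failed.

## Scope

Rooted trees only: cyclic and unrooted glycans, inner repeats, wildcard-bond
enumeration, non-sugar backbone components and SNFG raster images are out of
scope. Tree visualization is DOT text (`glycosmiles dot`), and the package
performs no semantic plausibility checks beyond atom existence — a valid
string that names rare chemistry is converted as written.
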