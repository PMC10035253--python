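"""Seeded random glycan generator.

Produces paired (IUPAC string, expected AST) corpora for fuzz testing the
parser and converter.  The generator only emits monomer/modification
combinations the template library declares chemically free — modifications
and child linkages are sampled from the unconsumed hydroxyl positions of
each base, so every generated string is convertible by construction and
never violates the one-modification-per-atom rule.  Invalid-input behavior
is exercised by hand-written tests instead.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field

from .glycan_ast import Anomer, GlycanNode, Linkage, ModificationSpec, serialize
from .modifications import FRAGMENTS
from .monomers import lookup_template

__all__ = ["FuzzConfig", "random_glycan", "generate_corpus", "write_corpus"]

_DEFAULT_MONOMERS = [
    "Glc", "Man", "Gal", "All", "Alt", "Gul", "Ido", "Tal",
    "Fuc", "Rha", "Qui", "Xyl", "Ara", "Rib", "Lyx",
]
_DEFAULT_MODIFICATIONS = ["S", "P", "Me", "Ac", "NAc", "d"]


@dataclass(frozen=True)
class FuzzConfig:
    """Knobs of the generator; probabilities are per free carbon position."""

    seed: int
    n_glycans: int = 1000
    max_depth: int = 5
    branch_probability: float = 0.3
    modification_probability: float = 0.2
    monomer_pool: list[str] = field(default_factory=lambda: list(_DEFAULT_MONOMERS))
    modification_pool: list[str] = field(
        default_factory=lambda: list(_DEFAULT_MODIFICATIONS))

    def __post_init__(self):
        if not 0 <= self.branch_probability <= 1:
            raise ValueError("branch_probability must be in [0, 1]")
        if not 0 <= self.modification_probability <= 1:
            raise ValueError("modification_probability must be in [0, 1]")
        if not self.monomer_pool:
            raise ValueError("monomer_pool must be non-empty")


def _free_positions(base: str) -> list[int]:
    return lookup_template(base).free_hydroxyl_positions()


def _spec(token: str, pos: int) -> ModificationSpec:
    frag = FRAGMENTS[token]
    return ModificationSpec(token, pos, frag.site_class, frag.action)


def _random_node(cfg: FuzzConfig, rng: random.Random, depth: int) -> GlycanNode:
    base = rng.choice(cfg.monomer_pool)
    free = _free_positions(base)

    deoxy_mods: list[ModificationSpec] = []
    suffix_mods: list[ModificationSpec] = []
    remaining: list[int] = []
    for pos in free:
        if rng.random() < cfg.modification_probability:
            candidates = [t for t in cfg.modification_pool
                          if t not in ("NAc", "N", "NS", "NMe") or pos == 2]
            token = rng.choice(candidates)
            if token == "d":
                deoxy_mods.append(_spec(token, pos))
            else:
                suffix_mods.append(_spec(token, pos))
        else:
            remaining.append(pos)

    prefix = "".join(f"{m.position}d" for m in deoxy_mods)
    suffix = "".join(f"{m.position}{m.token}" for m in suffix_mods)
    node = GlycanNode(raw_token=f"{prefix}{base}{suffix}", base_name=base,
                      modifications=deoxy_mods + suffix_mods)

    if depth < cfg.max_depth:
        for pos in remaining:
            if rng.random() < cfg.branch_probability:
                child = _random_node(cfg, rng, depth + 1)
                anomer = rng.choice([Anomer.ALPHA, Anomer.BETA])
                child.anomer = anomer
                link = Linkage(child_anomer=anomer, child_position=1,
                               parent_position=pos)
                node.children.append((link, child))
    return node


def random_glycan(config: FuzzConfig, index: int) -> tuple[str, GlycanNode]:
    """The ``index``-th glycan of the corpus: (iupac, expected AST).
    Deterministic in (seed, index)."""
    rng = random.Random((config.seed * 1_000_003 + index) % 2**31)
    ast = _random_node(config, rng, depth=1)
    return serialize(ast), ast


def generate_corpus(config: FuzzConfig):
    """Yield (iupac, expected AST) pairs, ``config.n_glycans`` of them."""
    for i in range(config.n_glycans):
        yield random_glycan(config, i)


def write_corpus(config: FuzzConfig, tsv_path, sidecar_path=None) -> int:
    """Write a two-column TSV (iupac, smiles) plus a JSON sidecar with the
    generator configuration; returns the number of rows written."""
    from .assemble import convert

    n = 0
    with open(tsv_path, "w") as fh:
        fh.write("iupac\tsmiles\n")
        for iupac, _ast in generate_corpus(config):
            fh.write(f"{iupac}\t{convert(iupac).smiles}\n")
            n += 1
    if sidecar_path is not None:
        cfg = {
            "seed": config.seed,
            "n_glycans": config.n_glycans,
            "max_depth": config.max_depth,
            "branch_probability": config.branch_probability,
            "modification_probability": config.modification_probability,
            "monomer_pool": config.monomer_pool,
            "modification_pool": config.modification_pool,
        }
        with open(sidecar_path, "w") as fh:
            json.dump(cfg, fh, indent=2)
    return n
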