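"""Subgroups of K4, orbit quotients, and the Delarue differentiation chain.

The Klein four-group has exactly five subgroups: the trivial group E, the
three order-2 subgroups T = {e,b} (transitions), A = {e,a} and AB = {e,ab},
and K4 itself.  A triple of subgroups, one per codon position, acts
component-wise on codon space; its orbits form a quotient partition.
Dividing N by T yields the purine/pyrimidine split {R, Y}; dividing by E
resolves single bases; dividing by K4 leaves a set whole.

Delarue's genealogy of the genetic code — a sequence of binary decisions
that progressively fix codon meaning, middle base first, wobble base last
— becomes, in this formulation, a chain of refining quotient partitions:
``NNN / K4TK4 → {NRN, NYN}``, then K4eK4, TeK4, eeK4, eeT and eee, with
the block count doubling at each of the six steps.  Three quaternary
steps (K4eK4, eeK4, eee) resolve one whole codon position at a time.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Optional

from .klein_group import (
    ALL_CODONS,
    DEFAULT_VARIANT,
    ELEMENTS,
    NUCLEOTIDES,
    CayleyVariant,
    InputError,
    act_on_codon,
    act_on_nucleotide,
    multiply,
)
from .code_tables import STOP_CODONS, standard_code

# --------------------------------------------------------------------------
# Subgroups
# --------------------------------------------------------------------------

SUBGROUPS: dict[str, frozenset[str]] = {
    "E": frozenset({"e"}),
    "T": frozenset({"e", "b"}),
    "A": frozenset({"e", "a"}),
    "AB": frozenset({"e", "ab"}),
    "K4": frozenset(ELEMENTS),
}

SUBGROUP_NAMES = tuple(SUBGROUPS)


def is_subgroup(elements: Iterable[str]) -> bool:
    """Closure-and-identity check for a subset of K4 (inverses are free:
    every element is its own inverse)."""
    s = frozenset(elements)
    if "e" not in s or not s <= frozenset(ELEMENTS):
        return False
    return all(multiply(x, y) in s for x in s for y in s)


def subgroup(name: str) -> frozenset[str]:
    try:
        return SUBGROUPS[name.upper() if name.lower() != "e" else "E"]
    except KeyError:
        raise InputError(f"unknown subgroup {name!r} (expected one of {SUBGROUP_NAMES})") from None


def parse_subgroup_triple(text: str) -> tuple[str, str, str]:
    """Parse compact positional notation like "K4TK4", "TeK4", "eee"."""
    names: list[str] = []
    i = 0
    s = text.strip()
    while i < len(s) and len(names) < 3:
        if s[i : i + 2].upper() == "K4":
            names.append("K4")
            i += 2
        elif s[i : i + 2].upper() == "AB":
            names.append("AB")
            i += 2
        elif s[i].upper() in ("E", "T", "A"):
            names.append("E" if s[i].upper() == "E" else s[i].upper())
            i += 1
        else:
            raise InputError(f"cannot parse subgroup triple {text!r} at position {i}")
    if len(names) != 3 or i != len(s):
        raise InputError(f"subgroup triple {text!r} must name exactly three subgroups")
    return tuple(names)  # type: ignore[return-value]


def format_subgroup_triple(names: Iterable[str]) -> str:
    return "".join("e" if n == "E" else n for n in names)


# --------------------------------------------------------------------------
# Orbits
# --------------------------------------------------------------------------


def nucleotide_orbits(
    s: str | frozenset[str], variant: CayleyVariant = DEFAULT_VARIANT
) -> tuple[frozenset[str], ...]:
    """Orbit partition of the four nucleotides under a subgroup of K4."""
    elements = subgroup(s) if isinstance(s, str) else frozenset(s)
    if not is_subgroup(elements):
        raise InputError(f"{sorted(elements)} is not a subgroup of K4")
    seen: set[str] = set()
    orbits: list[frozenset[str]] = []
    for n in NUCLEOTIDES:
        if n in seen:
            continue
        orbit = frozenset(act_on_nucleotide(g, n, variant) for g in elements)
        orbits.append(orbit)
        seen |= orbit
    return tuple(orbits)


def codon_orbit(
    codon: str, triple: tuple[str, str, str], variant: CayleyVariant = DEFAULT_VARIANT
) -> frozenset[str]:
    """Orbit of a codon under a subgroup triple acting component-wise."""
    groups = [subgroup(n) for n in triple]
    return frozenset(
        act_on_codon(gs, codon, variant) for gs in itertools.product(*groups)
    )


# --------------------------------------------------------------------------
# Quotient partitions and chains
# --------------------------------------------------------------------------

_PATTERN_LETTER = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("U"): "U",
    frozenset("AG"): "R", frozenset("CU"): "Y", frozenset("ACGU"): "N",
}


def block_name(block: frozenset[str]) -> str:
    """Pattern name of a codon block when it is a per-position product of
    base sets (NRN, NAN, RAN, ...); otherwise the lexicographically
    smallest member."""
    per_pos = [frozenset(c[i] for c in block) for i in range(3)]
    if all(s in _PATTERN_LETTER for s in per_pos):
        name = "".join(_PATTERN_LETTER[s] for s in per_pos)
        sizes = 1
        for s in per_pos:
            sizes *= len(s)
        if sizes == len(block):
            return name
    return min(block)


@dataclass(frozen=True)
class QuotientPartition:
    """A partition of codon space generated by a subgroup-triple quotient."""

    blocks: tuple[frozenset[str], ...]
    triple: Optional[tuple[str, str, str]]
    parent: Optional["QuotientPartition"] = None

    @property
    def block_names(self) -> tuple[str, ...]:
        return tuple(block_name(b) for b in self.blocks)

    def __len__(self) -> int:
        return len(self.blocks)

    def refines(self, other: "QuotientPartition") -> bool:
        return all(any(b <= p for p in other.blocks) for b in self.blocks)

    def annotate(self) -> dict[str, dict[str, object]]:
        """Amino acids and stop codons present in each block."""
        code = standard_code()
        out: dict[str, dict[str, object]] = {}
        for b in self.blocks:
            out[block_name(b)] = {
                "size": len(b),
                "amino_acids": sorted({code[c] for c in b} - {"STOP"}),
                "stop_codons": sorted(set(b) & STOP_CODONS),
            }
        return out


def root_partition() -> QuotientPartition:
    """The undifferentiated code: a single block NNN."""
    return QuotientPartition(blocks=(frozenset(ALL_CODONS),), triple=None, parent=None)


def refine(
    parent: QuotientPartition,
    triple: str | tuple[str, str, str],
    variant: CayleyVariant = DEFAULT_VARIANT,
) -> QuotientPartition:
    """Split every parent block into orbits of the subgroup triple.

    An orbit is intersected with the block it refines, so the result is
    always a refinement of the parent.
    """
    names = parse_subgroup_triple(triple) if isinstance(triple, str) else tuple(triple)
    new_blocks: list[frozenset[str]] = []
    for block in parent.blocks:
        seen: set[str] = set()
        for codon in sorted(block):
            if codon in seen:
                continue
            orbit = codon_orbit(codon, names, variant) & block  # type: ignore[arg-type]
            new_blocks.append(orbit)
            seen |= orbit
    return QuotientPartition(blocks=tuple(new_blocks), triple=names, parent=parent)  # type: ignore[arg-type]


BINARY_CHAIN_TRIPLES = ("K4TK4", "K4eK4", "TeK4", "eeK4", "eeT", "eee")
QUATERNARY_CHAIN_TRIPLES = ("K4eK4", "eeK4", "eee")


def delarue_chain(
    mode: str = "binary", variant: CayleyVariant = DEFAULT_VARIANT
) -> list[QuotientPartition]:
    """The quotient-group rendering of Delarue's differentiation genealogy.

    ``binary`` applies K4TK4, K4eK4, TeK4, eeK4, eeT, eee in order, doubling
    the block count at each step (1 → 2 → 4 → 8 → 16 → 32 → 64); the middle
    base differentiates first and the wobble base last.  ``quaternary``
    resolves one whole codon position per step with K4eK4, eeK4, eee
    (1 → 4 → 16 → 64).  The returned chain includes the root.
    """
    if mode == "binary":
        steps = BINARY_CHAIN_TRIPLES
    elif mode == "quaternary":
        steps = QUATERNARY_CHAIN_TRIPLES
    else:
        raise InputError(f"unknown Delarue chain mode {mode!r}")
    chain = [root_partition()]
    for step in steps:
        chain.append(refine(chain[-1], step, variant))
    return chain
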