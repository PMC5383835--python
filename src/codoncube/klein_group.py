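"""The Klein four-group and its action on nucleotides and codons.

The two elementary point-mutation types of RNA — transversions (purine ↔
pyrimidine) and transitions (purine ↔ purine, pyrimidine ↔ pyrimidine) —
are involutions: applying the same mutation twice restores the original
base.  Together with the identity and their composition they form
the Klein four-group K4 = {e, a, b, ab}, the symmetry group of a rectangle.
K4 acts on the four nucleotides {A, C, G, U}, and the direct cube K4³ acts
component-wise on the 64 codons.

A concrete action is fixed by assigning two of the three fixed-point-free
involutions of the nucleotide set to the generators ``a`` and ``b``; the
third is then forced to be ``ab``.  Such an assignment is a
:class:`CayleyVariant`.  The default variant takes ``a`` to be the
complementary transversion (A↔U, G↔C) and ``b`` the transition (A↔G, C↔U);
a second, "legacy" variant realising the complement as the composite
element ``ab`` is also provided, matching earlier hypercube formulations.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

logger = logging.getLogger("codoncube")

# --------------------------------------------------------------------------
# Group elements and multiplication
# --------------------------------------------------------------------------

ELEMENTS: tuple[str, ...] = ("e", "a", "b", "ab")
IDENTITY = "e"

# Multiplication table of (K4, ∘).  Composition is looked up, never derived
# by string concatenation.
_MULTIPLICATION: dict[tuple[str, str], str] = {
    ("e", "e"): "e", ("e", "a"): "a", ("e", "b"): "b", ("e", "ab"): "ab",
    ("a", "e"): "a", ("a", "a"): "e", ("a", "b"): "ab", ("a", "ab"): "b",
    ("b", "e"): "b", ("b", "a"): "ab", ("b", "b"): "e", ("b", "ab"): "a",
    ("ab", "e"): "ab", ("ab", "a"): "b", ("ab", "b"): "a", ("ab", "ab"): "e",
}


class InputError(ValueError):
    """Raised on malformed user input (unknown element, bad codon, ...)."""


def validate_element(x: str) -> str:
    if x not in ELEMENTS:
        raise InputError(f"unknown Klein group element: {x!r} (expected one of {ELEMENTS})")
    return x


def multiply(x: str, y: str) -> str:
    """Product x∘y in the Klein four-group."""
    validate_element(x)
    validate_element(y)
    return _MULTIPLICATION[(x, y)]


# --------------------------------------------------------------------------
# Nucleotides
# --------------------------------------------------------------------------

NUCLEOTIDES: tuple[str, ...] = ("A", "C", "G", "U")
PURINES = frozenset({"A", "G"})
PYRIMIDINES = frozenset({"C", "U"})


def normalize_base(symbol: str) -> str:
    """Validate a nucleotide symbol; DNA thymine is normalised to uracil."""
    s = symbol.upper()
    if s == "T":
        logger.warning("DNA base 'T' normalised to RNA 'U'")
        s = "U"
    if s not in NUCLEOTIDES:
        raise InputError(f"invalid nucleotide: {symbol!r}")
    return s


def normalize_codon(codon: str) -> str:
    """Validate a codon string (RNA, 5'→3'); T is normalised to U."""
    if not isinstance(codon, str) or len(codon) != 3:
        raise InputError(f"a codon must be a three-letter string, got {codon!r}")
    return "".join(normalize_base(ch) for ch in codon)


ALL_CODONS: tuple[str, ...] = tuple(
    "".join(bases) for bases in itertools.product(NUCLEOTIDES, repeat=3)
)
CODON_INDEX: Mapping[str, int] = {c: i for i, c in enumerate(ALL_CODONS)}

# --------------------------------------------------------------------------
# Cayley variants: assigning involutions to the generators
# --------------------------------------------------------------------------

# The three fixed-point-free involutions of {A, C, G, U}, written as sorted
# swap pairs.  Every Cayley variant distributes them over a, b and ab.
COMPLEMENT_TRANSVERSION = (("A", "U"), ("C", "G"))  # Watson–Crick complement
TRANSITION = (("A", "G"), ("C", "U"))
OTHER_TRANSVERSION = (("A", "C"), ("G", "U"))

_INVOLUTIONS = (COMPLEMENT_TRANSVERSION, TRANSITION, OTHER_TRANSVERSION)


def _involution_map(pairs: tuple[tuple[str, str], ...]) -> dict[str, str]:
    out: dict[str, str] = {}
    for x, y in pairs:
        out[x] = y
        out[y] = x
    return out


def _compose_involutions(p: tuple, q: tuple) -> tuple:
    pm, qm = _involution_map(p), _involution_map(q)
    mapped = {n: pm[qm[n]] for n in NUCLEOTIDES}
    pairs = sorted({tuple(sorted((n, m))) for n, m in mapped.items()})
    return tuple(pairs)


@dataclass(frozen=True)
class CayleyVariant:
    """An assignment of fixed-point-free involutions to the generators a, b.

    The involution realising ``ab`` is the composition of the two and is
    forced.  The Cayley graph on the nucleotides (edges = single-generator
    steps) is determined by which involution ends up as ``ab``.
    """

    name: str
    a: tuple[tuple[str, str], ...]
    b: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        for gen, pairs in (("a", self.a), ("b", self.b)):
            m = _involution_map(pairs)
            if sorted(m) != sorted(NUCLEOTIDES) or any(m[n] == n for n in m):
                raise InputError(f"generator {gen} is not a fixed-point-free involution: {pairs}")
        if self.a == self.b:
            raise InputError("generators a and b must carry distinct involutions")

    @property
    def ab(self) -> tuple[tuple[str, str], ...]:
        return _compose_involutions(self.a, self.b)

    def action_map(self, g: str) -> dict[str, str]:
        """The permutation of the nucleotides realised by group element g."""
        validate_element(g)
        if g == "e":
            return {n: n for n in NUCLEOTIDES}
        pairs = {"a": self.a, "b": self.b, "ab": self.ab}[g]
        return _involution_map(pairs)

    def graph_key(self) -> tuple:
        """Identifies the Cayley graph: the involution relegated to ab."""
        return self.ab


#: The standard action: a = complementary transversion, b = transition.
DEFAULT_VARIANT = CayleyVariant("standard", a=COMPLEMENT_TRANSVERSION, b=TRANSITION)

#: Earlier hypercube formulations realise the complement as the composite
#: element: a is the non-complementary transversion, b the transition, so
#: ab is the Watson–Crick complement.
LEGACY_VARIANT = CayleyVariant("legacy", a=OTHER_TRANSVERSION, b=TRANSITION)

_NAMED_VARIANTS = {"standard": DEFAULT_VARIANT, "legacy": LEGACY_VARIANT}


def get_variant(name: str) -> CayleyVariant:
    try:
        return _NAMED_VARIANTS[name]
    except KeyError:
        raise InputError(
            f"unknown Cayley variant {name!r} (expected one of {sorted(_NAMED_VARIANTS)})"
        ) from None


def enumerate_generator_assignments() -> tuple[CayleyVariant, ...]:
    """All 6 ordered assignments of two distinct involutions to (a, b)."""
    out = []
    for p, q in itertools.permutations(_INVOLUTIONS, 2):
        out.append(CayleyVariant(f"a={p},b={q}", a=p, b=q))
    return tuple(out)


def enumerate_cayley_variants() -> tuple[CayleyVariant, ...]:
    """The three essentially different Cayley graphs on the nucleotides.

    Six ordered generator assignments collapse to three graphs: swapping the
    roles of a and b leaves the edge set unchanged, so the graph only
    remembers which involution is relegated to the composite element ab.
    One canonical variant per graph is returned.
    """
    by_graph: dict[tuple, CayleyVariant] = {}
    for v in enumerate_generator_assignments():
        by_graph.setdefault(v.graph_key(), v)
    return tuple(by_graph.values())


def count_vertex_placements() -> int:
    """Number of ways to place the four nucleotides on four labelled rectangle vertices."""
    return sum(1 for _ in itertools.permutations(NUCLEOTIDES))


# --------------------------------------------------------------------------
# Group action on nucleotides and codons
# --------------------------------------------------------------------------

_action_cache: dict[CayleyVariant, dict[tuple[str, str], str]] = {}


def _action_table(variant: CayleyVariant) -> dict[tuple[str, str], str]:
    table = _action_cache.get(variant)
    if table is None:
        table = {}
        for g in ELEMENTS:
            m = variant.action_map(g)
            for n in NUCLEOTIDES:
                table[(g, n)] = m[n]
        _action_cache[variant] = table
    return table


def act_on_nucleotide(g: str, n: str, variant: CayleyVariant = DEFAULT_VARIANT) -> str:
    """Apply group element g to nucleotide n under the given variant."""
    validate_element(g)
    return _action_table(variant)[(g, normalize_base(n))]


def validate_triple(t: Iterable[str]) -> tuple[str, str, str]:
    triple = tuple(t)
    if len(triple) != 3:
        raise InputError(f"an action triple has exactly three components, got {triple!r}")
    for x in triple:
        validate_element(x)
    return triple  # type: ignore[return-value]


def act_on_codon(t: Iterable[str], codon: str, variant: CayleyVariant = DEFAULT_VARIANT) -> str:
    """Apply an action triple (a1, a2, a3) component-wise to a codon."""
    triple = validate_triple(t)
    c = normalize_codon(codon)
    table = _action_table(variant)
    return "".join(table[(g, n)] for g, n in zip(triple, c))


def multiply_triples(t1: Iterable[str], t2: Iterable[str]) -> tuple[str, str, str]:
    """Component-wise product of two action triples in K4³."""
    a = validate_triple(t1)
    b = validate_triple(t2)
    return tuple(multiply(x, y) for x, y in zip(a, b))  # type: ignore[return-value]


def all_action_triples() -> tuple[tuple[str, str, str], ...]:
    """All 64 elements of K4³, each its own inverse."""
    return tuple(itertools.product(ELEMENTS, repeat=3))  # type: ignore[return-value]


def triple_as_codon_map(
    t: Iterable[str], variant: CayleyVariant = DEFAULT_VARIANT
) -> dict[str, str]:
    """The permutation of the 64 codons realised by a fixed action triple."""
    triple = validate_triple(t)
    return {c: act_on_codon(triple, c, variant) for c in ALL_CODONS}
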