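"""The codon-space metric, the 6D hypercube graph and its automorphisms.

The mutation distance between two nucleotides is the minimum number of
generators (a or b) needed to turn one into the other: 0 for equal bases,
1 for a single-generator step, 2 when only the composite element ab
relates them.  Summing over the three codon positions gives a metric on
the 64 codons under which codon space is the 6-dimensional binary
hypercube Q6: each position contributes two binary coordinates, one
flipped by a and one flipped by b.

The graph automorphisms of Q6 — equivalently the isometries of the metric
— form the hyperoctahedral group Z2⁶ ⋊ S6 of order 46080; they are
materialised here explicitly as codon permutations via the binary
encoding.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import networkx as nx
import numpy as np

from .klein_group import (
    ALL_CODONS,
    CODON_INDEX,
    DEFAULT_VARIANT,
    NUCLEOTIDES,
    CayleyVariant,
    InputError,
    act_on_nucleotide,
    normalize_base,
    normalize_codon,
)

# --------------------------------------------------------------------------
# Metric
# --------------------------------------------------------------------------


def nucleotide_distance(x: str, y: str, variant: CayleyVariant = DEFAULT_VARIANT) -> int:
    """Generator-count distance between two nucleotides: 0, 1 or 2.

    1 when x = a·y or x = b·y; 2 when only the composite ab relates them.
    """
    x, y = normalize_base(x), normalize_base(y)
    if x == y:
        return 0
    if act_on_nucleotide("a", y, variant) == x or act_on_nucleotide("b", y, variant) == x:
        return 1
    return 2


def codon_distance(c1: str, c2: str, variant: CayleyVariant = DEFAULT_VARIANT) -> int:
    """Sum of per-position nucleotide distances; ranges over 0..6."""
    a, b = normalize_codon(c1), normalize_codon(c2)
    return sum(nucleotide_distance(x, y, variant) for x, y in zip(a, b))


def complement(codon: str) -> str:
    """Base-wise Watson–Crick complement (no reversal; codons stay 5'→3')."""
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    return "".join(comp[n] for n in normalize_codon(codon))


def max_complement_distance(variant: CayleyVariant = DEFAULT_VARIANT) -> int:
    """Max metric distance between a codon and its base-wise complement.

    Under the legacy variant, where the complement is realised by the
    composite element ab, every position contributes 2 and the maximum is 6.
    """
    return max(codon_distance(c, complement(c), variant) for c in ALL_CODONS)


# --------------------------------------------------------------------------
# Binary coordinates
# --------------------------------------------------------------------------


def _base_bits(variant: CayleyVariant) -> dict[str, tuple[int, int]]:
    # Regular action: every base is a^i b^j · C for unique (i, j); encode it
    # as (i, j).  An a-step then flips the first bit, a b-step the second.
    # Under the default variant this is (purine indicator, weak-pair
    # indicator): A=(1,1), G=(1,0), U=(0,1), C=(0,0).
    out: dict[str, tuple[int, int]] = {}
    for i, j in itertools.product((0, 1), repeat=2):
        n = "C"
        if i:
            n = act_on_nucleotide("a", n, variant)
        if j:
            n = act_on_nucleotide("b", n, variant)
        out[n] = (i, j)
    if len(out) != 4:
        raise InputError("variant action is not regular on the nucleotides")
    return out


def to_binary(codon: str, variant: CayleyVariant = DEFAULT_VARIANT) -> tuple[int, ...]:
    """6-bit coordinates of a codon; bits (2i-1, 2i) encode position i."""
    bits = _base_bits(variant)
    out: list[int] = []
    for n in normalize_codon(codon):
        out.extend(bits[n])
    return tuple(out)


def from_binary(bits: Sequence[int], variant: CayleyVariant = DEFAULT_VARIANT) -> str:
    """Inverse of :func:`to_binary`."""
    bits = tuple(bits)
    if len(bits) != 6 or any(b not in (0, 1) for b in bits):
        raise InputError(f"expected six bits in {{0,1}}, got {bits!r}")
    inverse = {v: k for k, v in _base_bits(variant).items()}
    return "".join(inverse[(bits[2 * i], bits[2 * i + 1])] for i in range(3))


def _bit_matrix(variant: CayleyVariant) -> np.ndarray:
    return np.array([to_binary(c, variant) for c in ALL_CODONS], dtype=np.uint8)


# --------------------------------------------------------------------------
# Hypercube graph
# --------------------------------------------------------------------------


def build_graph(variant: CayleyVariant = DEFAULT_VARIANT) -> nx.Graph:
    """The 64-codon graph with edges at metric distance 1.

    Edges are single-generator steps and are therefore variant-dependent;
    the graph records its variant in ``G.graph["variant"]``.  Each edge
    carries the generator name and the codon position it acts on; each
    vertex carries its 6-bit coordinate string.
    """
    g = nx.Graph(variant=variant.name)
    for c in ALL_CODONS:
        g.add_node(c, bits="".join(map(str, to_binary(c, variant))))
    for c in ALL_CODONS:
        for pos in range(3):
            for gen in ("a", "b"):
                n2 = act_on_nucleotide(gen, c[pos], variant)
                c2 = c[:pos] + n2 + c[pos + 1 :]
                if not g.has_edge(c, c2):
                    g.add_edge(c, c2, generator=gen, position=pos + 1)
    return g


# --------------------------------------------------------------------------
# Automorphisms
# --------------------------------------------------------------------------


def is_graph_automorphism(
    m: Mapping[str, str], g: nx.Graph
) -> tuple[bool, list[tuple[str, str]]]:
    """Check that a codon map is a bijection preserving adjacency both ways.

    Returns (verdict, violations); a violation is an edge whose image (or
    preimage under the inverse) is not an edge.
    """
    missing = [c for c in g.nodes if c not in m]
    if missing:
        raise InputError(f"codon map is partial; missing {len(missing)} codons, e.g. {missing[:3]}")
    values = set(m.values())
    if values != set(g.nodes):
        # not a bijection onto the vertex set: report the collapsed pairs
        seen: dict[str, str] = {}
        collisions = []
        for c in sorted(g.nodes):
            img = m[c]
            if img in seen:
                collisions.append((seen[img], c))
            seen[img] = c
        return False, collisions
    inv = {v: k for k, v in m.items()}
    violations: list[tuple[str, str]] = []
    for u, v in g.edges:
        if not g.has_edge(m[u], m[v]):
            violations.append((u, v))
        if not g.has_edge(inv[u], inv[v]):
            violations.append((u, v))
    return not violations, violations


@dataclass
class AutomorphismGroup:
    """The full automorphism group of the codon hypercube, materialised.

    Every automorphism of Q6 is a permutation of the six binary coordinates
    composed with a pattern of coordinate flips; realised on codons through
    the binary encoding these give |Z2⁶ ⋊ S6| = 46080 codon permutations.
    ``images[k, i]`` is the codon index of the image of codon i under map k.
    """

    variant: CayleyVariant
    images: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return self.images.shape[0]

    @property
    def order(self) -> int:
        return len(self)

    def as_codon_map(self, k: int) -> dict[str, str]:
        row = self.images[k]
        return {ALL_CODONS[i]: ALL_CODONS[row[i]] for i in range(64)}

    def __iter__(self) -> Iterator[dict[str, str]]:
        for k in range(len(self)):
            yield self.as_codon_map(k)

    def contains_map(self, m: Mapping[str, str]) -> bool:
        row = np.array([CODON_INDEX[m[c]] for c in ALL_CODONS], dtype=np.uint8)
        return bool((self.images == row).all(axis=1).any())


_aut_cache: dict[CayleyVariant, AutomorphismGroup] = {}


def enumerate_automorphism_group(variant: CayleyVariant = DEFAULT_VARIANT) -> AutomorphismGroup:
    """Materialise all 46080 hypercube automorphisms as codon permutations."""
    cached = _aut_cache.get(variant)
    if cached is not None:
        return cached
    bits = _bit_matrix(variant)  # (64, 6)
    weights = np.array([32, 16, 8, 4, 2, 1], dtype=np.int64)
    # index of each codon in bit-index space and back
    bit_index = bits @ weights  # codon i -> integer of its bits
    codon_of_bitindex = np.empty(64, dtype=np.uint8)
    codon_of_bitindex[bit_index] = np.arange(64, dtype=np.uint8)

    masks = ((np.arange(64)[:, None] >> np.arange(5, -1, -1)[None, :]) & 1).astype(np.uint8)
    blocks = []
    for perm in itertools.permutations(range(6)):
        permuted = bits[:, perm]  # (64, 6)
        imgs_bits = permuted[None, :, :] ^ masks[:, None, :]  # (64, 64, 6)
        imgs = imgs_bits.astype(np.int64) @ weights  # (64, 64) bit-index
        blocks.append(codon_of_bitindex[imgs])
    group = AutomorphismGroup(variant=variant, images=np.vstack(blocks))
    _aut_cache[variant] = group
    return group
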