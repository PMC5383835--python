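"""Piecewise codon isometries and their verification.

A :class:`PiecewiseMap` is a total map of codon space defined block-wise:
an ordered list of (pattern, action triple) rules whose domains partition
the 64 codons; the unique matching rule's triple is applied component-wise.
The built-in maps are:

* ``T1`` and ``T2`` — hypercube automorphisms that interchange the codons
  of aaRS class I with class II: T1 applies (a,b,a) on RNY∪YNR and (e,b,e)
  on RNR∪YNY; T2 applies (a,b,ab) on RNY∪YNR and (e,b,b) on RNR∪YNY.
* ``T3 = T1∘T2`` — the uniform triple (e,e,b), a transition in the wobble
  position, which leaves the classes invariant.
* ``F`` — the 16-block map that converts the middle-base partition
  {NAN, NGN, NUN, NCN} of the Rodin–Ohno arrangement into the
  purine/pyrimidine partition {RNR, YNR, RNY, YNY}, block by block.

Verification utilities check bijectivity, involutivity, graph-automorphism
status, class interchange/invariance against a two-class map, and exact
partition-onto-partition mapping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .klein_group import (
    ALL_CODONS,
    DEFAULT_VARIANT,
    CayleyVariant,
    InputError,
    act_on_codon,
    multiply_triples,
    normalize_codon,
    validate_triple,
)
from .code_tables import Classification, expand_pattern
from . import hypercube


class MapValidationError(InputError):
    """A piecewise map whose rule domains overlap or fail to cover."""


@dataclass(frozen=True)
class Rule:
    pattern: str
    triple: tuple[str, str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "triple", validate_triple(self.triple))
        expand_pattern(self.pattern)  # validates the pattern


@dataclass(frozen=True)
class PiecewiseMap:
    """A total codon map defined by disjoint, covering pattern rules."""

    name: str
    rules: tuple[Rule, ...]

    def __post_init__(self) -> None:
        rules = tuple(
            r if isinstance(r, Rule) else Rule(pattern=r[0], triple=tuple(r[1]))
            for r in self.rules
        )
        object.__setattr__(self, "rules", rules)
        covered: dict[str, str] = {}
        overlaps: set[str] = set()
        for rule in rules:
            for codon in expand_pattern(rule.pattern):
                if codon in covered:
                    overlaps.add(codon)
                covered[codon] = rule.pattern
        if overlaps:
            raise MapValidationError(
                f"map {self.name!r}: overlapping rule domains on {len(overlaps)} codons, "
                f"e.g. {sorted(overlaps)[:4]}"
            )
        missing = sorted(set(ALL_CODONS) - set(covered))
        if missing:
            raise MapValidationError(
                f"map {self.name!r}: rules leave {len(missing)} codons uncovered, "
                f"e.g. {missing[:4]}"
            )

    def rule_for(self, codon: str) -> Rule:
        codon = normalize_codon(codon)
        for rule in self.rules:
            if codon in expand_pattern(rule.pattern):
                return rule
        raise MapValidationError(f"map {self.name!r}: no rule covers {codon}")  # unreachable

    def apply(self, codon: str, variant: CayleyVariant = DEFAULT_VARIANT) -> str:
        return act_on_codon(self.rule_for(codon).triple, codon, variant)

    __call__ = apply

    def mapping(self, variant: CayleyVariant = DEFAULT_VARIANT) -> dict[str, str]:
        """The full codon → codon dictionary of the map."""
        return {c: self.apply(c, variant) for c in ALL_CODONS}

    def is_involution(self, variant: CayleyVariant = DEFAULT_VARIANT) -> bool:
        return all(self.apply(self.apply(c, variant), variant) == c for c in ALL_CODONS)

    def is_bijection(self, variant: CayleyVariant = DEFAULT_VARIANT) -> bool:
        return len(set(self.mapping(variant).values())) == 64


# --------------------------------------------------------------------------
# Built-in maps
# --------------------------------------------------------------------------

# The class-interchange rules are stated bidirectionally (RNY ↔ YNR under
# one self-inverse triple); internally each map expands to four one-way
# rules carrying the stated triple, which is an exact rewriting.


def make_T1() -> PiecewiseMap:
    return PiecewiseMap(
        "T1",
        (
            Rule("RNY", ("a", "b", "a")),
            Rule("YNR", ("a", "b", "a")),
            Rule("RNR", ("e", "b", "e")),
            Rule("YNY", ("e", "b", "e")),
        ),
    )


def make_T2() -> PiecewiseMap:
    return PiecewiseMap(
        "T2",
        (
            Rule("RNY", ("a", "b", "ab")),
            Rule("YNR", ("a", "b", "ab")),
            Rule("RNR", ("e", "b", "b")),
            Rule("YNY", ("e", "b", "b")),
        ),
    )


def make_T3() -> PiecewiseMap:
    """The uniform wobble transition (e, e, b) = T1∘T2."""
    return PiecewiseMap("T3", (Rule("NNN", ("e", "e", "b")),))


_F_RULES: tuple[tuple[str, tuple[str, str, str]], ...] = (
    ("RAR", ("e", "e", "e")),
    ("RGR", ("a", "b", "e")),
    ("YGR", ("e", "e", "e")),
    ("YAR", ("a", "b", "e")),
    ("RUY", ("e", "e", "e")),
    ("RCY", ("a", "b", "e")),
    ("YCY", ("e", "e", "e")),
    ("YUY", ("a", "b", "e")),
    ("RUR", ("e", "a", "a")),
    ("RCR", ("a", "ab", "a")),
    ("YCR", ("e", "a", "a")),
    ("YUR", ("a", "ab", "a")),
    ("RAY", ("e", "a", "a")),
    ("RGY", ("a", "ab", "a")),
    ("YGY", ("e", "a", "a")),
    ("YAY", ("a", "ab", "a")),
)


def make_F() -> PiecewiseMap:
    """The 16-block involution converting the middle-base partition into
    the purine/pyrimidine (first/third position) partition."""
    return PiecewiseMap("F", tuple(Rule(p, t) for p, t in _F_RULES))


def named_map(name: str) -> PiecewiseMap:
    makers = {"T1": make_T1, "T2": make_T2, "T3": make_T3, "F": make_F}
    try:
        return makers[name]()
    except KeyError:
        raise InputError(f"unknown built-in map {name!r} (expected one of {sorted(makers)})") from None


# --------------------------------------------------------------------------
# Composition
# --------------------------------------------------------------------------


def _pattern_name(block: frozenset[str]) -> str | None:
    """Name a codon set as a three-letter pattern if it is a per-position
    product of base sets; None otherwise."""
    letter = {
        frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("U"): "U",
        frozenset("AG"): "R", frozenset("CU"): "Y", frozenset("ACGU"): "N",
    }
    per_pos = [frozenset(c[i] for c in block) for i in range(3)]
    if any(s not in letter for s in per_pos):
        return None
    name = "".join(letter[s] for s in per_pos)
    return name if expand_pattern(name) == block else None


def compose(
    m1: PiecewiseMap,
    m2: PiecewiseMap,
    name: str | None = None,
    variant: CayleyVariant = DEFAULT_VARIANT,
) -> PiecewiseMap:
    """Point-wise composition: apply ``m1`` first, then ``m2``.

    The composite triple at a codon c is the component-wise K4 product of
    m1's triple at c and m2's triple at m1(c).  Codons are regrouped by
    composite triple, and each group is expressed as a pattern rule when it
    is pattern-expressible, falling back to one exact-codon rule per codon.
    """
    by_triple: dict[tuple[str, str, str], set[str]] = {}
    for c in ALL_CODONS:
        t1 = m1.rule_for(c).triple
        t2 = m2.rule_for(m1.apply(c, variant)).triple
        by_triple.setdefault(multiply_triples(t1, t2), set()).add(c)
    rules: list[Rule] = []
    for triple in sorted(by_triple):
        block = frozenset(by_triple[triple])
        pattern = _pattern_name(block)
        if pattern is not None:
            rules.append(Rule(pattern, triple))
        else:
            rules.extend(Rule(c, triple) for c in sorted(block))
    return PiecewiseMap(name or f"{m2.name}∘{m1.name}", tuple(rules))


# --------------------------------------------------------------------------
# Verification
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class IsometryReport:
    map_name: str
    is_bijection: bool
    is_involution: bool
    is_automorphism: bool
    violations: tuple[tuple[str, str], ...]

    @property
    def ok(self) -> bool:
        return self.is_bijection and self.is_automorphism


def verify_isometry(
    m: PiecewiseMap,
    graph: nx.Graph | None = None,
    variant: CayleyVariant = DEFAULT_VARIANT,
) -> IsometryReport:
    """Check bijectivity, involutivity and adjacency preservation."""
    g = graph if graph is not None else hypercube.build_graph(variant)
    mapping = m.mapping(variant)
    is_bij = len(set(mapping.values())) == 64
    if is_bij:
        is_auto, violations = hypercube.is_graph_automorphism(mapping, g)
    else:
        is_auto, violations = False, ()
    return IsometryReport(
        map_name=m.name,
        is_bijection=is_bij,
        is_involution=m.is_involution(variant),
        is_automorphism=is_auto,
        violations=tuple(violations),
    )


@dataclass(frozen=True)
class ClassReport:
    """Outcome of a class-interchange or class-invariance check.

    Each violation records (codon, its label, its image, the image's
    label); ``stop_involved`` lists the violations in which either end is a
    stop codon under the classification's stop flags.
    """

    map_name: str
    classification: str
    check: str
    violations: tuple[tuple[str, str, str, str], ...]
    skipped_unlabelled: tuple[str, ...] = ()
    stop_involved: tuple[tuple[str, str, str, str], ...] = ()

    @property
    def ok(self) -> bool:
        return not self.violations


def verify_class_interchange(
    m: PiecewiseMap,
    classes: Classification,
    variant: CayleyVariant = DEFAULT_VARIANT,
) -> ClassReport:
    """Every codon must map to the OTHER class; same-label images are violations."""
    labels = classes.label_set()
    if len(labels) != 2:
        raise InputError(
            f"class interchange needs a two-valued classification, got labels {labels}"
        )
    if classes.unlabelled:
        raise InputError("class interchange needs a total classification")
    violations = []
    for c in ALL_CODONS:
        img = m.apply(c, variant)
        if classes.labels[c] == classes.labels[img]:
            violations.append((c, classes.labels[c], img, classes.labels[img]))
    return _class_report(m, classes, "interchange", violations)


def verify_class_invariance(
    m: PiecewiseMap,
    classes: Classification,
    variant: CayleyVariant = DEFAULT_VARIANT,
) -> ClassReport:
    """Every labelled codon must map to the SAME label; unlabelled codons
    are skipped (and reported as skipped)."""
    violations = []
    skipped = []
    for c in ALL_CODONS:
        lab = classes.labels.get(c)
        if lab is None:
            skipped.append(c)
            continue
        img = m.apply(c, variant)
        img_lab = classes.labels.get(img)
        if img_lab is None:
            skipped.append(c)
            continue
        if lab != img_lab:
            violations.append((c, lab, img, img_lab))
    return _class_report(m, classes, "invariance", violations, tuple(skipped))


def _class_report(m, classes, check, violations, skipped=()):
    stops = classes.stop_flags
    violations = tuple(violations)
    return ClassReport(
        map_name=m.name,
        classification=classes.name,
        check=check,
        violations=violations,
        skipped_unlabelled=tuple(skipped),
        stop_involved=tuple(v for v in violations if v[0] in stops or v[2] in stops),
    )


@dataclass(frozen=True)
class PartitionMappingReport:
    map_name: str
    block_image_map: tuple[tuple[str, str | None], ...]
    exact: bool


def verify_partition_mapping(
    m: PiecewiseMap,
    source: Mapping[str, frozenset[str]],
    target: Mapping[str, frozenset[str]],
    variant: CayleyVariant = DEFAULT_VARIANT,
) -> PartitionMappingReport:
    """Does ``m`` send each source block exactly onto one target block?

    ``exact`` is True iff every source-block image equals a target block
    and the induced block correspondence is a bijection.
    """
    inverse_target = {block: name for name, block in target.items()}
    pairs: list[tuple[str, str | None]] = []
    hit: list[str] = []
    for name, block in source.items():
        image = frozenset(m.apply(c, variant) for c in block)
        tname = inverse_target.get(image)
        pairs.append((name, tname))
        if tname is not None:
            hit.append(tname)
    exact = all(t is not None for _, t in pairs) and sorted(hit) == sorted(target)
    return PartitionMappingReport(map_name=m.name, block_image_map=tuple(pairs), exact=exact)


# --------------------------------------------------------------------------
# File I/O
# --------------------------------------------------------------------------


def load_piecewise_map(path: str | Path, name: str | None = None) -> PiecewiseMap:
    """Load a piecewise map from JSON or TSV.

    JSON: ``{"name": ..., "rules": [{"pattern": "RNY", "triple": ["a","b","a"]}, ...]}``.
    TSV: lines ``pattern<TAB>a1,a2,a3`` (``#`` comments allowed).
    Totality and disjointness are validated; offending codons are named.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json" or text.lstrip().startswith("{"):
        doc = json.loads(text)
        rules = tuple(Rule(r["pattern"], tuple(r["triple"])) for r in doc["rules"])
        return PiecewiseMap(name or doc.get("name", path.stem), rules)
    rules_list: list[Rule] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise MapValidationError(f"{path}: line {lineno}: expected 'pattern<TAB>a1,a2,a3'")
        pattern, triple_txt = parts
        triple = tuple(x.strip() for x in triple_txt.split(","))
        rules_list.append(Rule(pattern.strip(), triple))  # type: ignore[arg-type]
    return PiecewiseMap(name or path.stem, tuple(rules_list))


def save_piecewise_map(m: PiecewiseMap, path: str | Path) -> None:
    path = Path(path)
    doc = {
        "name": m.name,
        "rules": [{"pattern": r.pattern, "triple": list(r.triple)} for r in m.rules],
    }
    path.write_text(json.dumps(doc, indent=2) + "\n")
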