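"""Built-in biological tables and classification I/O.

Holds the standard genetic code, the two-class partition of the
aminoacyl-tRNA synthetases (aaRSs), the purine/pyrimidine pattern
partitions of codon space, and a small TSV format for user-supplied
codon → label classifications.

The aaRS class map comes in two modes.  ``structural`` follows the
structure-based assignment of the twenty amino acids into two ten-member
classes; ``functional`` differs from it exactly on the ambiguous pair
Phe/Tyr (Phe → class I, Tyr → class II), the unique swap under which the
piecewise class-interchange maps of :mod:`codoncube.transformations`
exchange the classes without violation.  Stop codons are attached to class
I in both modes, reflecting that their documented captures by amino acids
are mostly class I; this stop policy is an interpretation, and the
verification reports flag stop-involving pairs distinctly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping

from .klein_group import (
    ALL_CODONS,
    InputError,
    NUCLEOTIDES,
    normalize_codon,
)

STOP = "STOP"

# --------------------------------------------------------------------------
# Standard genetic code (RNA codons, three-letter amino acid codes)
# --------------------------------------------------------------------------

_STANDARD_CODE: dict[str, str] = {
    # U-first
    "UUU": "Phe", "UUC": "Phe", "UUA": "Leu", "UUG": "Leu",
    "UCU": "Ser", "UCC": "Ser", "UCA": "Ser", "UCG": "Ser",
    "UAU": "Tyr", "UAC": "Tyr", "UAA": STOP, "UAG": STOP,
    "UGU": "Cys", "UGC": "Cys", "UGA": STOP, "UGG": "Trp",
    # C-first
    "CUU": "Leu", "CUC": "Leu", "CUA": "Leu", "CUG": "Leu",
    "CCU": "Pro", "CCC": "Pro", "CCA": "Pro", "CCG": "Pro",
    "CAU": "His", "CAC": "His", "CAA": "Gln", "CAG": "Gln",
    "CGU": "Arg", "CGC": "Arg", "CGA": "Arg", "CGG": "Arg",
    # A-first
    "AUU": "Ile", "AUC": "Ile", "AUA": "Ile", "AUG": "Met",
    "ACU": "Thr", "ACC": "Thr", "ACA": "Thr", "ACG": "Thr",
    "AAU": "Asn", "AAC": "Asn", "AAA": "Lys", "AAG": "Lys",
    "AGU": "Ser", "AGC": "Ser", "AGA": "Arg", "AGG": "Arg",
    # G-first
    "GUU": "Val", "GUC": "Val", "GUA": "Val", "GUG": "Val",
    "GCU": "Ala", "GCC": "Ala", "GCA": "Ala", "GCG": "Ala",
    "GAU": "Asp", "GAC": "Asp", "GAA": "Glu", "GAG": "Glu",
    "GGU": "Gly", "GGC": "Gly", "GGA": "Gly", "GGG": "Gly",
}

STOP_CODONS: frozenset[str] = frozenset(c for c, aa in _STANDARD_CODE.items() if aa == STOP)


def standard_code() -> dict[str, str]:
    """The standard genetic code: codon → 3-letter amino acid or STOP."""
    return dict(_STANDARD_CODE)


# --------------------------------------------------------------------------
# aaRS classes
# --------------------------------------------------------------------------

CLASS_I_STRUCTURAL = frozenset(
    {"Arg", "Cys", "Gln", "Glu", "Ile", "Leu", "Met", "Trp", "Tyr", "Val"}
)
CLASS_II_STRUCTURAL = frozenset(
    {"Ala", "Asn", "Asp", "Gly", "His", "Lys", "Phe", "Pro", "Ser", "Thr"}
)


@dataclass(frozen=True)
class AaRSClassMap:
    """Amino acid → aaRS class ("I" or "II"), with mode and stop policy."""

    mode: str
    amino_to_class: Mapping[str, str]
    stop_policy: str = "stops-to-class-I"

    def class_of(self, amino: str) -> str:
        if amino == STOP:
            return "I"
        try:
            return self.amino_to_class[amino]
        except KeyError:
            raise InputError(f"unknown amino acid {amino!r}") from None

    def members(self, cls: str) -> frozenset[str]:
        return frozenset(a for a, c in self.amino_to_class.items() if c == cls)


def aars_classes(mode: str = "structural") -> AaRSClassMap:
    """The two ten-member aaRS classes.

    ``structural``: the structure-based assignment.  ``functional``: the
    same assignment with the ambiguous pair swapped (Phe → I, Tyr → II).
    """
    if mode not in ("structural", "functional"):
        raise InputError(f"unknown aaRS class mode {mode!r}")
    mapping = {a: "I" for a in CLASS_I_STRUCTURAL}
    mapping.update({a: "II" for a in CLASS_II_STRUCTURAL})
    if mode == "functional":
        mapping["Phe"] = "I"
        mapping["Tyr"] = "II"
    return AaRSClassMap(mode=mode, amino_to_class=mapping)


# --------------------------------------------------------------------------
# Pattern partitions
# --------------------------------------------------------------------------

_PATTERN_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "U": frozenset("U"),
    "R": frozenset("AG"), "Y": frozenset("CU"), "N": frozenset("ACGU"),
}


@lru_cache(maxsize=None)
def expand_pattern(pattern: str) -> frozenset[str]:
    """All codons matching a three-letter pattern over {A,C,G,U,R,Y,N}."""
    if not isinstance(pattern, str) or len(pattern) != 3:
        raise InputError(f"a codon pattern must have three letters, got {pattern!r}")
    try:
        sets = [_PATTERN_SETS[ch.upper().replace("T", "U")] for ch in pattern]
    except KeyError as exc:
        raise InputError(f"invalid pattern letter in {pattern!r}: {exc}") from None
    return frozenset("".join(bases) for bases in itertools.product(*sets))


def matches_pattern(codon: str, pattern: str) -> bool:
    return normalize_codon(codon) in expand_pattern(pattern)


_TABLE5_PATTERNS = tuple(
    f"{p1}{mid}{p3}" for p1 in "RY" for mid in "AGUC" for p3 in "RY"
)

_SCHEMES: dict[str, tuple[str, ...]] = {
    "first-third-RY": ("RNY", "YNR", "RNR", "YNY"),
    "middle-base": ("NAN", "NGN", "NUN", "NCN"),
    "table5-blocks": _TABLE5_PATTERNS,
}


def pattern_blocks(scheme: str | Iterable[str]) -> dict[str, frozenset[str]]:
    """A named partition of the 64 codons into pattern blocks.

    ``scheme`` is one of "first-third-RY", "middle-base", "table5-blocks",
    or an explicit iterable of patterns.  The blocks must be pairwise
    disjoint and cover codon space.
    """
    if isinstance(scheme, str):
        try:
            patterns = _SCHEMES[scheme]
        except KeyError:
            raise InputError(
                f"unknown partition scheme {scheme!r} (expected one of {sorted(_SCHEMES)})"
            ) from None
    else:
        patterns = tuple(scheme)
    blocks = {p: expand_pattern(p) for p in patterns}
    covered: set[str] = set()
    for p, block in blocks.items():
        overlap = covered & block
        if overlap:
            raise InputError(f"pattern {p!r} overlaps earlier blocks on {sorted(overlap)[:4]}")
        covered |= block
    if covered != set(ALL_CODONS):
        missing = sorted(set(ALL_CODONS) - covered)
        raise InputError(f"patterns do not cover codon space; {len(missing)} missing, e.g. {missing[:4]}")
    return blocks


# --------------------------------------------------------------------------
# Classifications
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Classification:
    """A total or partial codon → label map, the object of symmetry scans."""

    name: str
    labels: Mapping[str, str]
    provenance: str = ""
    stop_flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for c, lab in self.labels.items():
            if c not in ALL_CODONS:
                raise InputError(f"invalid codon {c!r} in classification {self.name!r}")
            if not lab:
                raise InputError(f"empty label for codon {c} in classification {self.name!r}")

    def label_of(self, codon: str) -> str | None:
        return self.labels.get(normalize_codon(codon))

    @property
    def labelled(self) -> frozenset[str]:
        return frozenset(self.labels)

    @property
    def unlabelled(self) -> frozenset[str]:
        return frozenset(ALL_CODONS) - self.labelled

    def label_set(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.labels.values())))

    def blocks(self) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {}
        for c, lab in self.labels.items():
            out.setdefault(lab, set()).add(c)
        return {lab: frozenset(cs) for lab, cs in out.items()}


class ClassificationError(InputError):
    """Raised when a classification file is malformed; carries line details."""

    def __init__(self, message: str, lines: list[str] | None = None):
        self.lines = lines or []
        detail = "".join(f"\n  {line}" for line in self.lines)
        super().__init__(message + detail)


def read_classification_tsv(path: str | Path, name: str | None = None) -> Classification:
    """Read a two-column ``codon<TAB>label`` file; ``#`` starts a comment.

    DNA codons (with T) are accepted and normalised to RNA.  Duplicate
    codons, non-codon strings and empty labels are collected and reported
    with their line numbers.
    """
    path = Path(path)
    labels: dict[str, str] = {}
    problems: list[str] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            problems.append(f"line {lineno}: expected 'codon<TAB>label', got {raw!r}")
            continue
        codon_raw, label = parts[0].strip(), parts[1].strip()
        try:
            codon = normalize_codon(codon_raw)
        except InputError:
            problems.append(f"line {lineno}: invalid codon {codon_raw!r}")
            continue
        if not label:
            problems.append(f"line {lineno}: empty label for codon {codon_raw}")
            continue
        if codon in labels:
            problems.append(f"line {lineno}: duplicate codon {codon}")
            continue
        labels[codon] = label
    if problems:
        raise ClassificationError(f"invalid classification file {path}", problems)
    return Classification(
        name=name or path.stem, labels=labels, provenance=f"file:{path}",
        stop_flags=frozenset(STOP_CODONS) & set(labels),
    )


def write_classification_tsv(classes: Classification, path: str | Path) -> None:
    lines = [f"# classification: {classes.name}"]
    lines += [f"{c}\t{classes.labels[c]}" for c in ALL_CODONS if c in classes.labels]
    Path(path).write_text("\n".join(lines) + "\n")


def codon_classification(kind: str, source: str | Path | None = None) -> Classification:
    """A ready-made or file-loaded classification of the 64 codons.

    Kinds: ``aars-structural`` and ``aars-functional`` (labels I/II via the
    genetic code and the class map, stops → I); ``pr-default`` (the four
    middle-base 16-codon blocks, the natural four-way split of the hypercube
    into 4D subcubes used as default polarity categories, with stop codons
    flagged); ``user-file`` (TSV from ``source``).
    """
    if kind in ("aars-structural", "aars-functional"):
        cmap = aars_classes(kind.split("-", 1)[1])
        code = standard_code()
        labels = {c: cmap.class_of(code[c]) for c in ALL_CODONS}
        return Classification(
            name=kind, labels=labels,
            provenance=f"standard code + aaRS classes ({cmap.mode}; {cmap.stop_policy})",
            stop_flags=STOP_CODONS,
        )
    if kind == "pr-default":
        blocks = pattern_blocks("middle-base")
        labels = {c: pat for pat, block in blocks.items() for c in block}
        return Classification(
            name="pr-default", labels=labels,
            provenance="middle-base 4D subcube categories (default polarity split)",
            stop_flags=STOP_CODONS,
        )
    if kind == "user-file":
        if source is None:
            raise InputError("kind 'user-file' requires a source path")
        return read_classification_tsv(source)
    raise InputError(f"unknown classification kind {kind!r}")


# --------------------------------------------------------------------------
# Printed combinatorics of code space
# --------------------------------------------------------------------------


def possible_code_count() -> tuple[int, int]:
    """(number of codon → {20 amino acids + stop} assignments, the
    one-in-a-million share of them): 21⁶⁴ and 21⁶⁴ // 10⁶, exact."""
    total = 21 ** 64
    return total, total // 10 ** 6
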