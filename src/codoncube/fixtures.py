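"""Deterministic generation of synthetic test inputs.

Produces random codon classifications and random (valid) piecewise maps
for negative-control testing of the symmetry machinery, plus deliberately
broken files exercising the validation error paths.  All output is a pure
function of the seed.
"""

from __future__ import annotations

import random
from pathlib import Path

from .klein_group import ALL_CODONS, ELEMENTS
from .code_tables import Classification
from .transformations import PiecewiseMap, Rule

_CLASS_INTERCHANGE_PATTERNS = ("RNY", "YNR", "RNR", "YNY")


def random_classification(
    rng: random.Random, n_labels: int = 4, partial: bool = False, name: str = "random"
) -> Classification:
    """A classification assigning each codon one of ``n_labels`` labels
    uniformly; with ``partial`` roughly one codon in eight is left out."""
    labels = {}
    for c in ALL_CODONS:
        if partial and rng.random() < 0.125:
            continue
        labels[c] = f"L{rng.randrange(n_labels)}"
    return Classification(name=name, labels=labels, provenance="synthetic random")


def random_piecewise_map(rng: random.Random, name: str = "random-map") -> PiecewiseMap:
    """A valid piecewise map: one random action triple per block of the
    four-block purine/pyrimidine scheme."""
    rules = tuple(
        Rule(p, (rng.choice(ELEMENTS), rng.choice(ELEMENTS), rng.choice(ELEMENTS)))
        for p in _CLASS_INTERCHANGE_PATTERNS
    )
    return PiecewiseMap(name, rules)


def generate_fixtures(seed: int, n: int, out_dir: str | Path) -> list[Path]:
    """Write ``n`` random classification TSVs, ``n`` random piecewise-map
    JSONs, and three deliberately broken files; byte-identical per seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed)
    written: list[Path] = []

    for i in range(n):
        cls = random_classification(rng, n_labels=rng.randrange(2, 6), name=f"random-{i}")
        path = out / f"classification_{i}.tsv"
        lines = [f"# synthetic random classification (seed={seed})"]
        lines += [f"{c}\t{cls.labels[c]}" for c in ALL_CODONS if c in cls.labels]
        path.write_text("\n".join(lines) + "\n")
        written.append(path)

    for i in range(n):
        m = random_piecewise_map(rng, name=f"random-map-{i}")
        path = out / f"piecewise_map_{i}.tsv"
        lines = [f"# synthetic random piecewise map (seed={seed})"]
        lines += [f"{r.pattern}\t{','.join(r.triple)}" for r in m.rules]
        path.write_text("\n".join(lines) + "\n")
        written.append(path)

    broken = {
        "broken_overlap.tsv": "RNY\ta,b,a\nRNN\te,e,e\n",
        "broken_noncovering.tsv": "RNY\ta,b,a\n",
        "broken_badcodon.tsv": "AGX\tL0\nAGC\tL1\n",
    }
    for fname, text in broken.items():
        path = out / fname
        path.write_text(text)
        written.append(path)
    return written
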