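"""Shared fixtures: variants, graphs, built-in maps and classifications."""

from __future__ import annotations

import pytest

from codoncube import (
    ALL_CODONS,
    DEFAULT_VARIANT,
    LEGACY_VARIANT,
    Classification,
    build_graph,
    codon_classification,
    enumerate_automorphism_group,
    make_F,
    make_T1,
    make_T2,
    make_T3,
    standard_code,
)


@pytest.fixture(scope="session")
def variant():
    return DEFAULT_VARIANT


@pytest.fixture(scope="session")
def legacy_variant():
    return LEGACY_VARIANT


@pytest.fixture(scope="session")
def graph():
    return build_graph(DEFAULT_VARIANT)


@pytest.fixture(scope="session")
def automorphisms():
    return enumerate_automorphism_group(DEFAULT_VARIANT)


@pytest.fixture(scope="session")
def T1():
    return make_T1()


@pytest.fixture(scope="session")
def T2():
    return make_T2()


@pytest.fixture(scope="session")
def T3():
    return make_T3()


@pytest.fixture(scope="session")
def F():
    return make_F()


@pytest.fixture(scope="session")
def functional_classes():
    return codon_classification("aars-functional")


@pytest.fixture(scope="session")
def structural_classes():
    return codon_classification("aars-structural")


@pytest.fixture(scope="session")
def pr_classes():
    return codon_classification("pr-default")


# Synthetic four-category hydropathy-like grouping of the amino acids.
# The real hydropathy categorisation is not hard-coded anywhere in the
# package (it is a file-driven input); this stand-in has the two features
# that matter for wobble-transition symmetry: Ile and Met share a
# category, and Trp sits in the moderately-hydrophobic one.
SYNTHETIC_HYDROPATHY = {
    "Ile": "strongly-hydrophobic", "Val": "strongly-hydrophobic",
    "Leu": "strongly-hydrophobic", "Phe": "strongly-hydrophobic",
    "Met": "strongly-hydrophobic",
    "Ala": "moderately-hydrophobic", "Cys": "moderately-hydrophobic",
    "Trp": "moderately-hydrophobic", "Gly": "moderately-hydrophobic",
    "Thr": "neutral", "Ser": "neutral", "Tyr": "neutral",
    "Pro": "neutral", "His": "neutral",
    "Glu": "hydrophilic", "Gln": "hydrophilic", "Asp": "hydrophilic",
    "Asn": "hydrophilic", "Lys": "hydrophilic", "Arg": "hydrophilic",
}


def hydropathy_classification(uga_label: str) -> Classification:
    """Synthetic hydropathy classes; UGA carries ``uga_label``, the other
    stops stay labelled 'stop'."""
    code = standard_code()
    labels = {}
    for c in ALL_CODONS:
        aa = code[c]
        if aa == "STOP":
            labels[c] = uga_label if c == "UGA" else "stop"
        else:
            labels[c] = SYNTHETIC_HYDROPATHY[aa]
    return Classification(
        name=f"hydropathy-synthetic-UGA-{uga_label}",
        labels=labels,
        provenance="synthetic stand-in grouping",
        stop_flags=frozenset({"UAA", "UAG", "UGA"}),
    )


@pytest.fixture()
def hydropathy_uga_stop():
    return hydropathy_classification("stop")


@pytest.fixture()
def hydropathy_uga_moderate():
    return hydropathy_classification("moderately-hydrophobic")
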