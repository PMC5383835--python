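"""Symmetry scanning: which hypercube automorphisms respect a classification?

Given a codon → label classification (aaRS class, polarity category,
hydropathy, or a user file), every automorphism in a chosen universe —
either the 64 fixed action triples of K4³ or all 46080 hypercube
automorphisms — is classified as

* **label-preserving**: every codon maps to a codon with the same label
  (unlabelled codons map to unlabelled ones in strict mode);
* **block-permuting**: every label block maps setwise onto some label
  block, so the map induces a permutation of the labels;
* neither.

The label-preserving maps form a subgroup of the block-permuting maps,
and the induced label permutations form a group: for the default
middle-base polarity categories the full universe induces the dihedral
group of the square (order 8), and the stabiliser of one 16-codon
category restricted to that category is the symmetry group of the 4D
hypercube, S2 Wr S4 of order 384.

A permutation null model quantifies how exceptional a classification's
invariant-symmetry count is: labels are shuffled across codons (multiset
preserved) and the count of invariant action triples recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .klein_group import (
    ALL_CODONS,
    CODON_INDEX,
    DEFAULT_VARIANT,
    CayleyVariant,
    InputError,
    all_action_triples,
    triple_as_codon_map,
)
from .code_tables import Classification
from . import hypercube

UNIVERSES = ("action-triples", "full-hypercube-automorphisms")


def _label_array(classes: Classification) -> tuple[np.ndarray, tuple[str, ...]]:
    """Labels as small ints over codon indices; -1 marks unlabelled."""
    labels = classes.label_set()
    index = {lab: i for i, lab in enumerate(labels)}
    arr = np.full(64, -1, dtype=np.int64)
    for c, lab in classes.labels.items():
        arr[CODON_INDEX[c]] = index[lab]
    return arr, labels


def _universe_images(universe: str, variant: CayleyVariant) -> np.ndarray:
    """(M, 64) array: row k maps codon index i to codon index images[k, i]."""
    if universe == "action-triples":
        rows = []
        for t in all_action_triples():
            m = triple_as_codon_map(t, variant)
            rows.append([CODON_INDEX[m[c]] for c in ALL_CODONS])
        return np.array(rows, dtype=np.uint8)
    if universe == "full-hypercube-automorphisms":
        return hypercube.enumerate_automorphism_group(variant).images
    raise InputError(f"unknown universe {universe!r} (expected one of {UNIVERSES})")


@dataclass(frozen=True)
class SymmetryReport:
    classification: str
    universe: str
    n_maps: int
    label_preserving_count: int
    block_permuting_count: int
    induced_label_group: tuple[tuple[str, ...], ...]
    induced_group_order: int
    block_stabilizer_orders: Mapping[str, int]
    strict_unlabelled: bool

    def induced_permutations(self) -> list[dict[str, str]]:
        labels = sorted({lab for perm in self.induced_label_group for lab in perm})
        # rows are stored as images of the sorted label list
        return [dict(zip(labels, perm)) for perm in self.induced_label_group]


def scan(
    classes: Classification,
    universe: str = "action-triples",
    variant: CayleyVariant = DEFAULT_VARIANT,
    strict_unlabelled: bool = True,
) -> SymmetryReport:
    """Classify every automorphism in the universe against a classification.

    With ``strict_unlabelled`` (default) an automorphism only qualifies if
    it maps unlabelled codons among themselves; with the flag off,
    unlabelled codons are ignored entirely.
    """
    L, labels = _label_array(classes)
    imgs = _universe_images(universe, variant)
    Limg = L[imgs]  # (M, 64): label of the image of codon i under map k
    nlab = len(labels)

    labelled_cols = np.nonzero(L >= 0)[0]
    unlabelled_cols = np.nonzero(L < 0)[0]

    if strict_unlabelled:
        preserving = (Limg[:, labelled_cols] == L[labelled_cols]).all(axis=1)
        if unlabelled_cols.size:
            preserving &= (Limg[:, unlabelled_cols] == -1).all(axis=1)
    else:
        # ignore unlabelled codons: only labelled → labelled pairs constrain
        X = Limg[:, labelled_cols]
        preserving = ((X == L[labelled_cols]) | (X == -1)).all(axis=1)

    # block-permuting: the image label is constant on each label block and
    # the induced label map is a bijection (in non-strict mode, unlabelled
    # images are ignored and the induced partial map must be injective)
    M = imgs.shape[0]
    values = np.empty((M, nlab), dtype=np.int64)
    const = np.ones(M, dtype=bool)
    for li in range(nlab):
        cols = np.nonzero(L == li)[0]
        X = Limg[:, cols]
        if strict_unlabelled:
            const &= (X == X[:, :1]).all(axis=1)
            values[:, li] = X[:, 0]
        else:
            vmax = X.max(axis=1)
            const &= ((X == vmax[:, None]) | (X == -1)).all(axis=1)
            values[:, li] = vmax
    if strict_unlabelled:
        bijective = (np.sort(values, axis=1) == np.arange(nlab)).all(axis=1)
    else:
        sv = np.sort(values, axis=1)
        bijective = ~((sv[:, 1:] == sv[:, :-1]) & (sv[:, 1:] >= 0)).any(axis=1)
    permuting = const & bijective
    if strict_unlabelled and unlabelled_cols.size:
        permuting &= (Limg[:, unlabelled_cols] == -1).all(axis=1)

    perm_rows = values[permuting]
    if perm_rows.size:
        perm_rows = perm_rows[(perm_rows >= 0).all(axis=1)]  # full label permutations only
    unique_perms = np.unique(perm_rows, axis=0) if perm_rows.size else np.empty((0, nlab))
    induced = tuple(tuple(labels[v] for v in row) for row in unique_perms.astype(int))

    stab_orders: dict[str, int] = {}
    for li, lab in enumerate(labels):
        cols = np.nonzero(L == li)[0]
        fixing = permuting & (values[:, li] == li)
        restricted = imgs[fixing][:, cols]
        stab_orders[lab] = (
            int(np.unique(restricted, axis=0).shape[0]) if restricted.size else 0
        )

    return SymmetryReport(
        classification=classes.name,
        universe=universe,
        n_maps=int(M),
        label_preserving_count=int(preserving.sum()),
        block_permuting_count=int(permuting.sum()),
        induced_label_group=induced,
        induced_group_order=len(induced),
        block_stabilizer_orders=stab_orders,
        strict_unlabelled=strict_unlabelled,
    )


def invariant_actions(
    classes: Classification, variant: CayleyVariant = DEFAULT_VARIANT
) -> list[tuple[str, str, str]]:
    """Action triples whose codon maps never move a labelled codon across
    labels (unlabelled codons are skipped).  Always a subgroup of K4³."""
    L, _ = _label_array(classes)
    imgs = _universe_images("action-triples", variant)
    out = []
    triples = all_action_triples()
    labelled = L >= 0
    for k, t in enumerate(triples):
        img = imgs[k]
        both = labelled & labelled[img]
        if (L[img][both] == L[both]).all():
            out.append(t)
    return out


@dataclass(frozen=True)
class NullSummary:
    classification: str
    observed: int
    replicates: tuple[int, ...]
    seed: int

    @property
    def fraction_ge_observed(self) -> float:
        if not self.replicates:
            return float("nan")
        return sum(1 for r in self.replicates if r >= self.observed) / len(self.replicates)


def null_distribution(
    classes: Classification,
    n: int,
    seed: int,
    variant: CayleyVariant = DEFAULT_VARIANT,
) -> NullSummary:
    """Permutation null for the invariant-action count.

    Each replicate shuffles the labels across the labelled codons (the
    label multiset — the category sizes — is preserved; unlabelled codons
    stay unlabelled), isolating the arrangement of labels on the hypercube
    from their composition.
    """
    if n < 1:
        raise InputError("null_distribution requires n >= 1 replicates")
    L, labels = _label_array(classes)
    imgs = _universe_images("action-triples", variant)
    labelled_idx = np.nonzero(L >= 0)[0]

    def count(Lvec: np.ndarray) -> int:
        labelled = Lvec >= 0
        c = 0
        for k in range(imgs.shape[0]):
            img = imgs[k]
            both = labelled & labelled[img]
            if (Lvec[img][both] == Lvec[both]).all():
                c += 1
        return c

    observed = count(L)
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n):
        shuffled = L.copy()
        shuffled[labelled_idx] = rng.permutation(L[labelled_idx])
        reps.append(count(shuffled))
    return NullSummary(
        classification=classes.name, observed=observed, replicates=tuple(reps), seed=seed
    )
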