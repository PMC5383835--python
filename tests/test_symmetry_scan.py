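"""Symmetry scans, invariant action triples and the permutation null."""

import random

import pytest

from codoncube import (
    ALL_CODONS,
    Classification,
    InputError,
    invariant_actions,
    null_distribution,
    read_classification_tsv,
    scan,
    write_classification_tsv,
)
from codoncube.klein_group import all_action_triples, multiply_triples, triple_as_codon_map
from codoncube.fixtures import random_classification

from conftest import hydropathy_classification


# ----------------------------------------------------------------- scan


def test_pr_categories_have_square_symmetry_under_full_universe(pr_classes):
    report = scan(pr_classes, universe="full-hypercube-automorphisms")
    # interchanging whole categories realises the dihedral group of the square
    assert report.induced_group_order == 8
    perms = {perm: None for perm in report.induced_label_group}
    assert len(perms) == 8
    # closed under composition: composing any two induced permutations stays inside
    labels = sorted(pr_classes.label_set())
    as_maps = [dict(zip(labels, perm)) for perm in report.induced_label_group]
    for p in as_maps:
        for q in as_maps:
            composed = tuple(q[p[lab]] for lab in labels)
            assert composed in perms
    # non-abelian of order 8 on 4 points: the dihedral group
    found_noncommuting = any(
        tuple(q[p[lab]] for lab in labels) != tuple(p[q[lab]] for lab in labels)
        for p in as_maps
        for q in as_maps
    )
    assert found_noncommuting


def test_each_pr_block_stabilizer_restricts_to_the_4d_hypercube_group(pr_classes):
    report = scan(pr_classes, universe="full-hypercube-automorphisms")
    # |S2 Wr S4| = 2^4 · 4! = 384 for every 16-codon category
    assert set(report.block_stabilizer_orders.values()) == {384}


def test_pr_categories_under_action_triples(pr_classes):
    report = scan(pr_classes, universe="action-triples")
    assert report.n_maps == 64
    # the 64 triples always permute the middle-base blocks; the induced
    # permutations are the regular K4 action on the four bases
    assert report.block_permuting_count == 64
    assert report.induced_group_order == 4
    assert report.label_preserving_count == 16  # (g1, e, g3) triples


def test_unique_labels_leave_only_the_identity(variant):
    cls = Classification("all-distinct", {c: c for c in ALL_CODONS})
    report = scan(cls, universe="action-triples")
    assert report.label_preserving_count == 1
    report_full = scan(cls, universe="full-hypercube-automorphisms")
    assert report_full.label_preserving_count == 1


def test_label_preserving_maps_are_a_subset_of_block_permuting(pr_classes, functional_classes):
    for cls in (pr_classes, functional_classes):
        for universe in ("action-triples", "full-hypercube-automorphisms"):
            report = scan(cls, universe=universe)
            assert report.label_preserving_count <= report.block_permuting_count


def _naive_counts(cls, variant):
    """Per-map, per-codon reference check over the 64 action triples."""
    preserving = permuting = 0
    labels = cls.labels
    for t in all_action_triples():
        m = triple_as_codon_map(t, variant)
        ok_preserve = all(labels.get(c) == labels.get(m[c]) for c in ALL_CODONS)
        preserving += ok_preserve
        block_images = {}
        ok_permute = True
        for c in ALL_CODONS:
            lab = labels.get(c)
            img_lab = labels.get(m[c])
            block_images.setdefault(lab, set()).add(img_lab)
        image_of = {}
        for lab, imgs in block_images.items():
            if len(imgs) != 1:
                ok_permute = False
                break
            image_of[lab] = next(iter(imgs))
        if ok_permute:
            ok_permute = sorted(map(str, image_of.values())) == sorted(map(str, image_of))
        permuting += ok_permute
    return preserving, permuting


def test_scan_agrees_with_naive_oracle_on_action_triples(variant):
    rng = random.Random(1729)
    cases = [random_classification(rng, n_labels=k, name=f"r{k}") for k in (2, 3, 4)]
    from codoncube import codon_classification

    cases.append(codon_classification("pr-default"))
    cases.append(codon_classification("aars-functional"))
    for cls in cases:
        report = scan(cls, universe="action-triples", variant=variant)
        naive_preserving, naive_permuting = _naive_counts(cls, variant)
        assert report.label_preserving_count == naive_preserving
        assert report.block_permuting_count == naive_permuting


def test_scan_preserving_count_matches_invariant_actions_for_total(functional_classes):
    report = scan(functional_classes, universe="action-triples")
    assert report.label_preserving_count == len(invariant_actions(functional_classes))


def test_strict_versus_ignoring_unlabelled_codons():
    labels = {c: "x" for c in ALL_CODONS if c[2] in "UC"}  # wobble Y codons only
    cls = Classification("partial", labels)
    strict = scan(cls, universe="action-triples", strict_unlabelled=True)
    loose = scan(cls, universe="action-triples", strict_unlabelled=False)
    assert strict.label_preserving_count <= loose.label_preserving_count
    # (e, e, a) moves wobble U to A (labelled → unlabelled): passes only loosely
    assert loose.label_preserving_count == 64  # a single label, ignoring the rest
    assert strict.label_preserving_count == 32  # wobble component must fix {U, C}


# ----------------------------------------------------------------- invariants


def test_invariant_actions_for_functional_classes(functional_classes):
    inv = invariant_actions(functional_classes)
    assert ("e", "e", "e") in inv
    assert ("e", "e", "b") in inv  # the wobble transition T3
    assert len(inv) == 2


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
@pytest.mark.parametrize("partial", [False, True])
def test_invariant_actions_always_form_a_subgroup(seed, partial):
    rng = random.Random(seed)
    cls = random_classification(rng, n_labels=3, partial=partial, name=f"s{seed}")
    inv = invariant_actions(cls)
    assert ("e", "e", "e") in inv
    inv_set = set(inv)
    for t1 in inv_set:
        for t2 in inv_set:
            assert multiply_triples(t1, t2) in inv_set


def test_single_label_classification_is_invariant_under_everything():
    cls = Classification("uniform", {c: "only" for c in ALL_CODONS})
    assert len(invariant_actions(cls)) == 64


# ----------------------------------------------------------------- hydropathy file


def test_wobble_transition_invariance_requires_uga_reassignment(
    tmp_path, hydropathy_uga_stop, hydropathy_uga_moderate
):
    # With UGA kept as a stop the UGA/UGG wobble pair straddles two labels
    assert ("e", "e", "b") not in invariant_actions(hydropathy_uga_stop)
    # Relabelling UGA as moderately hydrophobic (alongside Trp) restores it
    path = tmp_path / "hydropathy_synthetic.tsv"
    write_classification_tsv(hydropathy_uga_moderate, path)
    cls = read_classification_tsv(path, name="hydropathy-synthetic")
    inv = invariant_actions(cls)
    assert ("e", "e", "b") in inv
    inv_set = set(inv)
    for t1 in inv_set:
        for t2 in inv_set:
            assert multiply_triples(t1, t2) in inv_set


def test_hydropathy_relabelling_differs_only_at_uga():
    a = hydropathy_classification("stop").labels
    b = hydropathy_classification("moderately-hydrophobic").labels
    assert {c for c in ALL_CODONS if a[c] != b[c]} == {"UGA"}


# ----------------------------------------------------------------- null model


def test_null_requires_at_least_one_replicate(functional_classes):
    with pytest.raises(InputError):
        null_distribution(functional_classes, n=0, seed=1)


def test_single_label_null_is_degenerate():
    cls = Classification("uniform", {c: "only" for c in ALL_CODONS})
    summary = null_distribution(cls, n=5, seed=7)
    assert summary.observed == 64
    assert set(summary.replicates) == {64}


def test_null_is_deterministic_given_seed(functional_classes):
    s1 = null_distribution(functional_classes, n=50, seed=42)
    s2 = null_distribution(functional_classes, n=50, seed=42)
    assert s1.replicates == s2.replicates
    assert s1.observed == s2.observed == 2
    # random arrangements of a 2-class labelling essentially never admit a
    # non-identity invariant symmetry
    assert max(s1.replicates) <= s1.observed


def test_null_preserves_label_multiset_interpretation(pr_classes):
    # shuffled labels keep the 16/16/16/16 composition, so the identity
    # is always invariant and every count is at least 1
    summary = null_distribution(pr_classes, n=20, seed=3)
    assert summary.observed >= 16
    assert all(r >= 1 for r in summary.replicates)
    assert 0.0 <= summary.fraction_ge_observed <= 1.0
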