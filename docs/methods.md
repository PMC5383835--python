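# Methods

## The group and its action

The package models point mutation of RNA bases with the Klein four-group
K4 = {e, a, b, ab}: every non-identity element is a fixed-point-free
involution of the nucleotide set N = {A, C, G, U}, and the group is
abelian. The multiplication table is stored explicitly and composition
is always a table lookup; element names are never manipulated as
strings.

There are exactly three fixed-point-free involutions of a 4-set: the
complementary transversion (A↔U, G↔C), the transition (A↔G, C↔U) and the
non-complementary transversion (A↔C, G↔U). A **Cayley variant** assigns
two of them to the generators a and b; the third is forced to be ab.
Ordered assignments number 3 × 2 = 6, but the Cayley graph on the
nucleotides (edges = single-generator steps) only remembers which
involution was relegated to the composite element, so exactly three
essentially different graphs exist. Two are named:

* **standard** (the default): a = complementary transversion,
  b = transition. One generator step takes a base to its complement.
* **legacy**: a = non-complementary transversion, b = transition, so the
  complement is the composite ab and costs two steps. This reproduces
  earlier hypercube formulations, in which a codon and its base-wise
  complement always sit at the maximum distance 6.

All operations take the variant explicitly and default to standard.
"Anticodon" claims about distance are interpreted against the base-wise
complementary codon, not the reversed complement: reversal is a
reading-order convention that the position-wise metric deliberately does
not model, and all output codons are rendered 5′→3′.

## Metric, binary encoding and the hypercube

Nucleotide distance is the minimum number of generators needed to mutate
one base into another (0, 1, or 2); codon distance is the sum over the
three positions. Each position contributes two bits — flipped by a and
by b respectively — via the regular action: base n = aⁱbʲ·C is encoded
(i, j), with C as origin. Under the standard variant this reduces to
familiar chemistry: bit 1 is the purine indicator (A,G → 1), bit 2 the
weak-pair indicator (A,U → 1). Codon distance then equals Hamming
distance on 6 bits, and codon space is the graph Q6: 64 vertices of
degree 6, 192 edges. The edge set depends on the variant (an edge is a
single-generator step); every exported graph is labelled with its
variant.

The automorphism group of Q6 is the hyperoctahedral group Z2⁶ ⋊ S6,
order 46080. It is materialised eagerly as all 46080 codon permutations
(a 46080 × 64 uint8 array, ~3 MB): at this size explicit enumeration is
cheaper and more transparent than lazy group machinery, and every
downstream symmetry count is an exact, exhaustive computation. A
vectorised adjacency oracle in the tests independently confirms each
enumerated map preserves all 192 edges, and the group order is
cross-checked against a permutation-group computation built from
generators.

## aaRS classes, the ambiguous pair and stop codons

The twenty amino acids split into two ten-member aaRS classes. The
**structural** mode stores the structure-based assignment
(class I: Arg, Cys, Gln, Glu, Ile, Leu, Met, Trp, Tyr, Val). The
**functional** mode differs from it exactly on the ambiguous pair,
putting Phe in class I and Tyr in class II. Whether the ambiguity of
that pair means "swapped" was settled empirically, not presumed: the
swap is the unique reading under which the piecewise maps T1 and T2
interchange the two classes with zero violations, and the structural
reading leaves a deterministic eight-codon violation set
(the Phe/Tyr codons and their interchange partners, the Ser/Cys codons
UCU, UCC, UGU, UGC) which is locked in the regression tests rather than
hidden.

Stop codons are attached to class I in both modes. The choice is an
interpretation motivated by the documented captures of stop codons being
mostly by class-I amino acids, and it is load-bearing: the
zero-violation interchange result depends on it, so the verification
reports flag every stop-involving pair distinctly instead of silently
excluding stops. The stop triplets are UAA, UAG and UGA, the standard
code's; sources that list UUA among the stops conflict with the standard
table (UUA is Leu) and internal consistency of the code table wins.

## Piecewise maps

A piecewise map is an ordered rule list (pattern → action triple) whose
domains must partition the 64 codons; construction validates totality
and disjointness, so rule application never needs a tie-break.
Bidirectional rule statements (RNY ↔ YNR under one self-inverse triple)
are expanded into one-way rules carrying the same triple, which is exact
because every triple is its own inverse. Composition is computed
point-wise and regrouped: codons are partitioned by composite triple and
each part is emitted as a pattern rule when it is a per-position product
of base sets, with exact-codon rules as the always-total fallback.

T1, T2, T3 and F are verified — not assumed — to be total, bijective,
involutive graph automorphisms; the checks are exhaustive over 64 codons
and 192 edges and run in milliseconds.

## Quotient chains

The five subgroups of K4 (E, T = {e,b}, A = {e,a}, AB = {e,ab}, K4) act
position-wise through subgroup triples written in compact positional
notation (K4TK4, TeK4, eee, ...). Refining a partition by a triple
splits every block into orbit intersections, so each step refines its
parent by construction. The binary differentiation chain applies K4TK4,
K4eK4, TeK4, eeK4, eeT, eee in that order — block counts 1, 2, 4, 8,
16, 32, 64, middle base first, wobble base last — and the quaternary
chain K4eK4, eeK4, eee resolves one position per step. Blocks are named
by their pattern string whenever they are pattern-expressible (every
block in these chains is), with the lexicographically smallest member as
fallback. Which stop codons sit in which block is reported as annotation
only, since no rule ties particular stops to particular branches. The
historical genealogy is usually described with five binary choices; the
algebraic chain here has six products because the wobble assignment is
itself rendered as a quotient step.

## Symmetry scans and the null model

A scan classifies every automorphism of a chosen universe — the 64 fixed
action triples, or all 46080 hypercube automorphisms — against a
codon → label classification as label-preserving, block-permuting
(every label block lands setwise on a label block), or neither.
Partial overlaps disqualify: permuting *whole* categories is the
property of interest. Unlabelled codons must map among themselves by
default; a flag relaxes this to ignoring them entirely. The
block-permuting maps induce a permutation group on the labels; for the
default polarity categories this group has order 8 and is non-abelian on
four points, i.e. Dih4, and the per-category stabiliser restricted to
its 16 codons has order 384 = 2⁴·4!, the symmetry group S2 Wr S4 of the
4-dimensional subcube. Both orders are computed by enumeration, not
asserted.

The **pr-default** classification is the four middle-base blocks: the
unique natural split of the 6-cube into four 16-codon 4D subcubes, used
as the default polarity categorisation. The exact published
category-colour membership (and likewise any hydropathy
categorisation) is not hard-coded anywhere: such schemes are
file-driven inputs via the classification TSV, and the tests use a
synthetic hydropathy-like stand-in grouping whose only load-bearing
features are that Ile and Met share a category and that relabelling UGA
into the moderately-hydrophobic category (alongside Trp) makes the
wobble transition (e,e,b) an invariant symmetry.

The null model shuffles labels across the labelled codons with a seeded
generator, preserving the label multiset (category sizes), and
recomputes the invariant-action count per replicate. Holding the
multiset fixed isolates the *arrangement* of labels on the cube from
their composition. The generator emulates arbitrary label arrangements
only; it does not model amino-acid chemistry, codon usage or
phylogenetic correlation, so a passing null comparison speaks to the
combinatorial exceptionality of an arrangement, not to any evolutionary
mechanism.

## Numerical and design choices

* Everything is exact integer/combinatorial computation; there are no
  tolerances. Determinism is total given the seed.
* Fixture generation (random classifications, random piecewise maps,
  deliberately broken files) is a pure function of its seed and is
  byte-identical across runs.
* Problem sizes are the natural ones of the object: 64 codons, 192
  edges, 64 action triples, 46080 automorphisms; every "for all" in the
  documentation is an exhaustive loop, and the full test suite runs in a
  few seconds.
* The classification TSV reader is hand-written because its job is
  line-level validation (duplicate codons, bad bases, empty labels
  reported with line numbers), not tabular parsing.
* DOT export is written directly (the format is trivial); GraphML goes
  through networkx.

## Limitations

* Only K4 and K4³ are supported; this is not a general finite-group
  library, and automorphism enumeration exploits the Q6 product
  structure rather than implementing general graph-automorphism search.
* Only the standard genetic code is built in; mitochondrial and other
  variant codes are out of scope.
* The stop-codon class policy and the functional Phe/Tyr reading are
  interpretations (documented above); users can test alternatives by
  supplying their own classification files.
* Numeric polarity or hydropathy scales, error-minimisation scoring of
  code efficiency, and anticodon-side conventions are out of scope; the
  package counts symmetries.
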