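# codoncube

Group-theoretic structure of the standard genetic code: the Klein
four-group acting on nucleotides, the 64 codons as a six-dimensional
hypercube, the piecewise isometries that exchange the two
aminoacyl-tRNA-synthetase (aaRS) classes, the quotient-group rendering of
Delarue's differentiation genealogy, and a general symmetry scanner for
codon classifications.

It is aimed at researchers in molecular evolution and mathematical
biology who want to compute with — rather than merely look at — the
symmetries of the codon table.

## The model

The two elementary point mutations of RNA are involutions: a transversion
*a* (here the complementary transversion A↔U, G↔C) and a transition *b*
(A↔G, C↔U). With the identity *e* and the composite *ab* they form the
Klein four-group K4 = {e, a, b, ab}, which acts on the nucleotide set
N = {A, C, G, U}, and whose direct cube K4³ acts component-wise on the 64
codons: ((a₁,a₂,a₃), x₁x₂x₃) ↦ (a₁x₁, a₂x₂, a₃x₃).

Distance between nucleotides is the minimum number of generators needed
to mutate one into the other (0, 1, or 2); summing over the three codon
positions makes codon space a metric space isometric to the binary
6-cube Q6. Its graph automorphisms — the hyperoctahedral group
Z2⁶ ⋊ S6, order 46080 — are the symmetries the package searches.

On this cube the package provides:

* **T1, T2** — piecewise automorphisms (e.g. T1 applies (a,b,a) on
  RNY∪YNR and (e,b,e) on RNR∪YNY) that interchange the codons of aaRS
  class I with class II, and their composition **T3 = (e,e,b)**, a
  wobble-position transition that leaves the classes invariant.
* **F** — a 16-block involution converting the middle-base partition
  {NAN, NGN, NUN, NCN} of the Rodin–Ohno codon arrangement exactly onto
  the purine/pyrimidine partition {RNR, YNR, RNY, YNY}.
* **Quotient chains** — dividing codon space by subgroup triples such as
  K4TK4 (T = {e,b}, the transitions) reproduces Delarue's genealogy as six
  binary refinements 1 → 2 → 4 → 8 → 16 → 32 → 64, or three quaternary
  ones 1 → 4 → 16 → 64.
* **Symmetry scans** — for any codon → label classification, the
  automorphisms that preserve every label or permute whole label blocks,
  the induced permutation group on the labels, and a permutation null
  model for how exceptional the observed symmetry is.

## Worked example

```python
>>> from codoncube import act_on_codon, make_F, make_T1, make_T2, compose
>>> act_on_codon(("a", "ab", "a"), "AGC")   # AGC lies in the RGY block
'UUG'
>>> act_on_codon(("a", "ab", "a"), "UUG")   # the same action sends it back
'AGC'
>>> compose(make_T1(), make_T2()).rules     # T1∘T2 is one uniform rule
(Rule(pattern='NNN', triple=('e', 'e', 'b')),)
```

Every component of an action triple is its own inverse, so the worked
transformation AGC → UUG is reversed by applying the identical triple.
The composite of the two class-interchange maps collapses to the single
wobble transition (e,e,b): exchanging the aaRS classes twice leaves each
class fixed while transiting the third base.

```python
>>> from codoncube import codon_classification, scan
>>> report = scan(codon_classification("pr-default"),
...               universe="full-hypercube-automorphisms")
>>> report.induced_group_order, set(report.block_stabilizer_orders.values())
(8, {384})
```

The four 16-codon middle-base categories (the default polarity split)
can only be permuted like the corners of a square — the induced label
group has order 8, the dihedral group Dih4 — while the stabiliser of one
category, restricted to it, is the full symmetry group of a 4-dimensional
hypercube, S2 Wr S4 of order 384.

The same operations are scriptable from the shell:

```sh
$ codoncube transform --map F AGC
AGC	UUG
$ codoncube delarue --mode binary | head -3
root: 1 blocks: NNN
  K4TK4: 2 blocks: NRN, NYN
    K4eK4: 4 blocks: NAN, NGN, NCN, NUN
$ codoncube verify T1 --class-mode functional   # exit 0: perfect interchange
```

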