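# mma-kit

An executable algebra kit for a structure-mapping model of analogy, written
for computational cognitive scientists who want analogical-transfer claims to
be *checkable* rather than narrative.  The kit models a domain of knowledge
as a pair (A, Π): a carrier set A generated from a few seed elements by the
operations that a finite set Π of first-order terms induces.  An analogy from
(A, Π) to (B, Ψ) is a pair (F, h) where F : Π → Ψ translates each schema term
to one with the same variables and h : A → B satisfies, for every t ∈ Π and
all a₁…aₙ ∈ A,

    h(f_t(a₁, …, aₙ)) = f_F(t)(h(a₁), …, h(aₙ)).

Given images for the generators, h is forced — or provably impossible, in
which case the kit returns a conflict witness: one element with two
derivations whose transferred images disagree.  On top of this sit the
symbolic (free) domains Π*(X), kernel partitions of interpretation maps
(whose classes are re-representation classes: all syntactically different
terms with one meaning), quotient domains with the coequalizer's universal
property made executable, and a first-isomorphism-theorem checker.

Three worked cognitive models ship with the kit:

* **board games** — the numbered linear game as a certified isomorphism
  between a spatial domain (ten boxes) and the numbers 1–10, with an
  exhaustive 10² commutation census; the circular board's broken distance
  and order structure, derived from its geometry;
* **a kinship riddle** ("two fathers and two sons, but only three men") —
  kernel quotients of the paternal and maternal term languages, the induced
  class-level map, and the contrast with unification-style partitions;
* **fraction learning** — procedural knowledge (exact normalization, the
  quotient map) versus conceptual knowledge (interpretation through a
  "pizza" domain of exact positive rationals), their provable agreement, and
  an analysis of the classic mediant error 1/2 + 1/2 = 2/4.

## Worked example

Proportional analogies a : b :: c : ? are YAML problem files; five classic
letter-string problems are bundled.  The copycat-style problem
*aabc : aabd :: ijkk : ?* is modelled with append + letter-successor on the
source side, translated to swapped-append + letter-predecessor:

```sh
$ mma solve src/mma/data/example_0_5.yaml
example_0_5: aabc : aabd :: ijkk : ?
  example_0_5: hjkk
```

The answer `hjkk` is h(aabd) for the unique homomorphism with h(a) = k; the
solver also confirms h(aabc) = ijkk (the consistency flag).  A problem with
no structure-preserving solution reports its witness instead:

```sh
$ mma solve src/mma/data/example_0_6.yaml
example_0_6: ababa : abbaa :: cdcdg : ?
  example_0_6: no solution -- conflicting images cdcdgcdcdgg vs cdcdggdcdcg at ababaababaa
```

Case studies print their own reports:

```sh
$ mma casestudy fractions
mediant_restricted_merged_classes:
- - '1'
  - 1/2
procedural_conceptual_checked: 9000
procedural_conceptual_disagreements: 0
```

meaning: on the enumerated fragment of 9000 fraction terms the procedural
and conceptual routes to meaning never disagree, and the buggy mediant rule
conflates the number classes [1] and [1/2].  `mma casestudy board-game`,
`mma casestudy riddle`, `mma check-diagram riddle` and `mma gen --seed N`
cover the other models; the same functionality is available as a library
(`mma.case_studies`, `mma.rerepresentation`, `mma.problems`).

All certificates are relative to explicit enumeration bounds (closure depth,
element size, element and application counts); every report carries a
`truncated` flag because the underlying domains are typically infinite.

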