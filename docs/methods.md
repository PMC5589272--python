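# Methods

## The model

A *context* is a K-algebra: a carrier of tagged values with one partial
operation per function symbol.  A finite set Π of first-order terms over a
context's signature induces a family of operations f_t — evaluate t under an
assignment of its variables (taken in canonical order: name prefix, then
numeric suffix).  A *domain* (A, Π) is the closure of a generator set A₀
under {f_t}.  An analogy is an F-homomorphism: a variable-preserving term
translation F : Π → Ψ together with an element map h satisfying
h(f_t(ā)) = f_F(t)(h(ā)) for every application.  The *symbolic* domain
(Π*(X), Π) is the free counterpart whose elements are terms and whose
operations are substitutions; a term morphism F* extends F to it by
outermost decomposition and recursion.

Everything the kit certifies is certified *at bounds*: the closures are
infinite in general, so enumeration stops at a configurable derivation
depth, element size, element count and application count, and every report
carries a `truncated` flag (with `caps_hit` distinguishing a hard stop from
an ordinary depth limit).  A certificate therefore reads "no counterexample
among all N enumerated applications", which is the strongest statement an
executable checker can make about an infinite object.

## Key algorithmic decisions

**Closure and derivation index.**  `generate_closure` enumerates layer by
layer (layer d applies each f_t to tuples of elements first seen before
layer d) in canonical order, so output is reproducible bit for bit.  Every
application is logged and up to 8 derivations per element are retained;
element identity is carrier-value equality, *not* derivation identity —
this is precisely what makes conflicting derivations detectable.
Applications yielding the undefined value are counted and discarded.

**Homomorphism extension.**  Generator images are propagated along the
application log in closure order.  If two derivations of one element force
different images, the extension fails with a witness holding the element,
both derivations and both images; processing order makes the witness the
minimal-depth, canonically-first conflict.  Equality of partial results is
Kleene equality throughout (both undefined counts as equal).  An
independent depth-first propagation over first derivations exists solely so
tests can confirm the extension is order-independent.

**Term morphisms.**  F* is computed by nonlinear outermost pattern
matching: a decomposition of a term against a schema term counts only when
every bound subterm is itself generated by the schema; if two valid
decompositions yield different images the table is marked inconsistent with
a witness rather than assuming well-definedness.

**Quotients.**  Kernel partitions are fibers of an interpretation map, with
canonical minimal representatives.  Induced class operations are verified
by exhaustive re-evaluation over member tuples within the fragment (capped
at 200,000 checks); tuples whose results escape the fragment impose no
constraint, which is the bounded reading of the infinite quotient.  The
coequalizer factorization u∘π = z is constructed when z is constant on
classes and refuted with a two-member witness otherwise — a result value,
not an exception, since "does this evaluator respect the kernel?" is a
question the fraction error analysis asks in earnest.

**Sorts.**  Boolean-valued relations live in the same machinery as
carrier-valued operations; values are tagged and each operation declares
argument/result sorts.  The closure and fragment enumerators skip
sort-incompatible tuples, while calling an operation directly with a
mis-sorted value is a contract error, deliberately distinct from the
undefined outcome of a partial operation.

## Case-study encodings

**Board game.**  Numbers 1..n form the numeric carrier; successor(n) and a
zero distance are undefined, mirroring the spatial side (there is no box
after the last one on a linear board, and no box 0 to stand for a
zero-length stroll).  With this pairing the interpretation diagram commutes
under Kleene equality for all n² token assignments, which the census checks
exhaustively.  The circular analysis is geometric: boxes sit evenly on a
unit circle, distance is chord length, and "left of" means "within the half
turn ahead", the convention that yields the documented paradox (box 1 left of
2, box 10 left of both).

**Riddle.**  Two three-person chains (Marius–Paul–Angelo and
Mary–Paula–Angela), paternal and maternal signatures of four symbols plus
truth constants, and the resolving assignment α (S₁ and F₂ both name the
middle man).  Quotients and diagram checks run on the person sort at
fragment depth 3 — the depth at which all tabulated class members appear —
and the boolean sort is reported separately, since relation terms inflate
the fragment quadratically without adding classes.

**Fractions.**  Literal tokens m/n are *variables* of the language; the
interpretation maps give them rational meaning, so distinct tokens (1/1 and
2/2) can share a kernel class — the re-representation content.  The
exhaustive two-route check runs on literals with numerator and denominator
at most 3 and term trees of depth at most 3 where one operand of the outer
operation is a literal (the shape of every tabulated entry): 9000 terms,
checked in under a second; wider literal ranges appear in targeted checks.
The mediant ("add tops and bottoms") evaluator works on written
numerator/denominator pairs, so it distinguishes 2/4 from 1/2 — which is
exactly why it fails to respect the kernel on any fragment containing both,
while on the minimal fragment {1/2, 1/2+1/2} it factors through the
quotient and conflates the classes [1] and [1/2].  The inverse translation
required by the conceptual route exists because the fraction translation is
constructed bijective.

## Synthetic problems

The planted generator draws a random schema over append/reversal, random
short generators, and pushes generators through a random permutation of the
alphabet letters in use.  Letterwise injections commute with append and
reversal, so the planted map is a genuine homomorphism by construction and
its full value table is the recovery oracle.  The successor operation is
deliberately excluded from random schemas — it does not commute with
arbitrary letter maps, and including it would break the planted guarantee.
What these fixtures do **not** emulate: noisy or partially observed
generator maps, competing modelings of one surface problem, or any search
over representations; passing recovery tests shows the deterministic
extension machinery is sound, not that representation discovery works.

## Problem sizes and defaults

Closure bounds default to depth 4, element size 64, 20,000 elements,
200,000 applications, 8 stored derivations per element.  Bundled problems
carry explicit depths (2–4), chosen as the smallest depth containing all
query items.  The oracle-equivalence suite uses 30 seeded schemas at depth
3 with element size 24 and roomy count caps so both enumerations reach the
same fixpoint; planted recovery uses 50 seeds at depth 3.  The riddle
fragment is depth 3; the fraction diagram uses four literal tokens at depth
2, where the quotient has 45 classes.

## Known limitations

* Certification never extends past the stated bounds; a conflict deeper
  than the enumeration horizon is invisible (the `truncated` flag marks
  exactly when this caveat applies).
* The generator map h′ must be supplied; there is no search over candidate
  maps or candidate schemas.
* Terms are first order; higher-order representations used by some symbolic
  models of analogy are out of scope.
* The well-definedness and morphism checks are capped for large fragments;
  reports record how many tuples were actually checked.
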