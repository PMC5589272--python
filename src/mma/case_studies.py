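"""Executable cognitive case studies: board games and fraction learning.

Board games
-----------
The numbered linear board game is modelled as an F-homomorphism from a
spatial domain (ten boxes; step right, stroll distance, left-of, tie) to a
numerical domain (numbers 1..10; successor, |X-Y|, <, =) sending box i to
number i.  The map is an isomorphism, and the interpretation diagram commutes
for every one of the 10^2 possible bindings of the two token variables X and
Y -- :func:`commutation_census` enumerates them all.  The circular board
breaks exactly the distance and order structure: with boxes evenly on a unit
circle, chord distances disagree with index distances, and any left/right
criterion produces an ordering cycle (:func:`circular_board_report`).

Fractions
---------
The "area model" teaching strategy is modelled with a pizza domain (exact
positive rationals with put_together / share_between / smaller_than) and the
fraction language (literals m/n with +, /, <).  Two routes send a symbolic
fraction term to its meaning: *procedural* knowledge is the quotient map
(exact evaluation, classes keyed by reduced fractions) and *conceptual*
knowledge is the composite through the pizza domain (inverse-translate,
interpret, map back).  The two routes agree on the whole enumerated fragment;
buggy procedures (the mediant "add tops and bottoms" rule) are analysed by
asking whether they factor through the quotient at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from itertools import product
from typing import Callable, Iterable, Sequence

from .contexts import (
    UNDEFINED,
    Context,
    Value,
    board_positions,
    box_value,
    builtin_context,
    integer_value,
    rational_value,
)
from .domain_closure import (
    Bounds,
    Domain,
    DomainSpec,
    evaluate_interpretation,
    generate_closure,
)
from .hom_solver import (
    Homomorphism,
    IsoReport,
    check_isomorphism,
    extend_homomorphism,
    generator_map,
)
from .quotient_coeq import Interpretation, Partition, kernel_partition
from .term_core import (
    App,
    Signature,
    Symbol,
    Term,
    TermTranslation,
    Var,
    extend_term_morphism,
    make_translation,
    parse_term,
    render,
    term_key,
)

# ---------------------------------------------------------------------------
# Board games.


@dataclass
class BoardModel:
    spatial: Domain
    numeric: Domain
    F: TermTranslation
    h: Homomorphism
    variables: tuple[str, str] = ("X", "Y")

    @property
    def n(self) -> int:
        return self.spatial.context.n_boxes  # type: ignore[attr-defined]


def numbered_game_model(n: int = 10) -> BoardModel:
    """The numbered linear game: box i -> number i, certified isomorphism."""
    spatial_ctx = builtin_context("board", n=n, shape="linear")
    numeric_ctx = builtin_context("numbers", n=n)
    xy = ["X", "Y"]
    sp = lambda s: parse_term(s, spatial_ctx.signature, xy)
    np_ = lambda s: parse_term(s, numeric_ctx.signature, xy)
    pi = (sp("go_to_right(X)"), sp("stroll_distance(X, Y)"), sp("left_of(X, Y)"), sp("tie(X, Y)"))
    psi = (np_("successor(X)"), np_("abs_diff(X, Y)"), np_("lt(X, Y)"), np_("eq(X, Y)"))
    F = make_translation(list(zip(pi, psi)))
    boxes = tuple(box_value(i) for i in range(1, n + 1))
    numbers = tuple(integer_value(i) for i in range(1, n + 1))
    spatial = generate_closure(DomainSpec(spatial_ctx, pi, boxes, "boxes"), Bounds(depth=2))
    numeric = generate_closure(DomainSpec(numeric_ctx, psi, numbers, "numbers"), Bounds(depth=2))
    h = extend_homomorphism(
        spatial, numeric, F, generator_map({b: k for b, k in zip(boxes, numbers)})
    )
    return BoardModel(spatial, numeric, F, h)


def commutation_census(
    m: BoardModel, mapping: dict[Value, Value] | None = None
) -> tuple[int, int, list]:
    """Check beta(F(t)) == h(alpha(t)) for all n^2 token assignments.

    Returns (commuting count, total count, failing (assignment, term) pairs).
    ``mapping`` overrides h's element map (used for sabotage experiments).
    """
    hmap = mapping if mapping is not None else m.h.mapping
    n = m.n
    failures = []
    commuting = 0
    total = 0
    for i in range(1, n + 1):
        for j in range(1, n + 1):
            total += 1
            alpha = {"X": box_value(i), "Y": box_value(j)}
            beta = {v: hmap[a] for v, a in alpha.items()}
            ok = True
            for t in m.spatial.spec.pi:
                left = evaluate_interpretation(m.numeric.context, m.F.apply(t), beta)
                a_t = evaluate_interpretation(m.spatial.context, t, alpha)
                right = hmap[a_t] if a_t.tag != "undefined" else UNDEFINED
                if left != right:
                    ok = False
                    failures.append(((i, j), t, left, right))
            if ok:
                commuting += 1
    return commuting, total, failures


@dataclass
class CircularReport:
    n: int
    chord: dict[tuple[int, int], float]
    distance_violations: list[tuple[int, int, int]]
    left_of: dict[tuple[int, int], bool]
    order_cycle: list[int]

    @property
    def has_paradox(self) -> bool:
        return bool(self.distance_violations) and bool(self.order_cycle)


def circular_board_report(n: int = 10, shape: str = "circular") -> CircularReport:
    """Geometric analysis of a circular (or linear control) board.

    Distances are straight-line (chord) lengths; left/right is the
    categorical coding "j is within the half turn ahead of i".  A violation
    triple (i, j, k) records |i-j| < |i-k| by index but chord(i,j) >
    chord(i,k) by geometry.
    """
    if n < 3:
        raise ValueError("need at least three boxes")
    pos = board_positions(n, shape)

    def chord(i: int, j: int) -> float:
        (xi, yi), (xj, yj) = pos[i], pos[j]
        return math.hypot(xi - xj, yi - yj)

    chords = {(i, j): chord(i, j) for i in pos for j in pos if i != j}
    violations = []
    for i in pos:
        for j in pos:
            for k in pos:
                if len({i, j, k}) < 3:
                    continue
                if abs(i - j) < abs(i - k) and chords[(i, j)] > chords[(i, k)] + 1e-12:
                    violations.append((i, j, k))
    if shape == "circular":
        left = {
            (i, j): 0 < ((j - i) % n) < n / 2 for i in pos for j in pos if i != j
        }
    else:
        left = {(i, j): i < j for i in pos for j in pos if i != j}
    cycle: list[int] = []
    if shape == "circular":
        walk = list(range(1, n + 1)) + [1]
        if all(left[(walk[i], walk[i + 1])] for i in range(len(walk) - 1)):
            cycle = walk
    return CircularReport(n, chords, violations, left, cycle)


# ---------------------------------------------------------------------------
# Fractions.

FRACTION_VARS_DEFAULT = 3  # literals m/n with m, n <= 3 in the enumerated fragment


def _fraction_language() -> tuple[Context, tuple[Term, ...], tuple[Term, ...], TermTranslation]:
    ctx = builtin_context("rationals")
    xy = ["X", "Y"]
    p = lambda s: parse_term(s, ctx.signature, xy)
    pi = (p("put_together(X, Y)"), p("share_between(X, Y)"), p("smaller_than(X, Y)"))
    psi = (p("plus(X, Y)"), p("div(X, Y)"), p("lt(X, Y)"))
    F = make_translation(list(zip(pi, psi)))
    return ctx, pi, psi, F


def fraction_literals(max_nd: int = FRACTION_VARS_DEFAULT) -> list[str]:
    return [f"{m}/{n}" for m in range(1, max_nd + 1) for n in range(1, max_nd + 1)]


@dataclass
class FractionModel:
    context: Context  # exact rationals; both vocabularies
    pi: tuple[Term, ...]  # pizza schema
    psi: tuple[Term, ...]  # fraction-language schema
    F: TermTranslation  # pizza -> fraction language
    literals: list[str]

    @property
    def Finv(self) -> TermTranslation:
        return self.F.inverse()

    def signature(self) -> Signature:
        return self.context.signature

    def parse(self, text: str) -> Term:
        """Parse a fraction-language term; literals m/n are the variables."""
        import re

        found = re.findall(r"\d+/\d+", text)
        return parse_term(text, self.context.signature, set(self.literals) | set(found))

    def literal_value(self, name: str) -> Value:
        m, n = name.split("/")
        return rational_value(Fraction(int(m), int(n)))

    def assignment(self, t: Term) -> dict[str, Value]:
        from .term_core import variables_of

        return {v: self.literal_value(v) for v in variables_of(t)}


def fraction_model(max_nd: int = FRACTION_VARS_DEFAULT) -> FractionModel:
    ctx, pi, psi, F = _fraction_language()
    return FractionModel(ctx, pi, psi, F, fraction_literals(max_nd))


def fraction_procedural_normalize(model: FractionModel, t: Term) -> Value:
    """pi_beta followed by the canonical representative: exact evaluation.

    This is the procedural route -- "apply the standard algorithms" -- and
    returns the reduced fraction (or boolean) keying the term's equivalence
    class, or the undefined value for division by zero.
    """
    return evaluate_interpretation(model.context, t, model.assignment(t))


def fraction_conceptual_eval(model: FractionModel, t: Term) -> Value:
    """The conceptual route c . alpha . F^-1*: through the pizza domain.

    The term is translated back into the pizza language by the inverse term
    morphism, interpreted there (put_together of two half pizzas...), and the
    resulting quantity is mapped to its class representative (c = b^-1 . h is
    the identity on reduced fractions under this encoding).
    """
    table = extend_term_morphism(model.Finv, [t])
    pizza_term = table.apply(t)
    return evaluate_interpretation(model.context, pizza_term, model.assignment(pizza_term))


def enumerate_fraction_fragment(
    model: FractionModel, depth: int = 3, literals: Sequence[str] | None = None
) -> list[Term]:
    """Fraction-language terms of tree depth <= ``depth`` over the literals.

    Depth counts a literal as 1.  At depth 3 -- the shape of every tabulated
    worked example -- one operand of the outer operation is a depth-2 term
    and the other a literal, in either order.
    """
    lits = [Var(v) for v in (literals if literals is not None else model.literals)]
    syms = [model.context.signature[s.symbol.name] for s in model.psi]
    rational_syms = [s for s in syms if model.context.result_sort(s.name) == "rational"]
    out: list[Term] = list(lits)
    if depth < 2:
        return out
    flat = [App(s, (a, b)) for s in syms for a in lits for b in lits]
    out.extend(flat)
    if depth < 3:
        return out
    inner = [t for t in flat if t.symbol in rational_syms]
    for s in syms:
        for c in inner:
            for l in lits:
                out.append(App(s, (c, l)))
                out.append(App(s, (l, c)))
    return out


def eq19_check(
    model: FractionModel, fragment: Iterable[Term]
) -> tuple[int, list[Term]]:
    """Exhaustive procedural-vs-conceptual agreement on a fragment (Kleene)."""
    checked = 0
    disagreements = []
    for t in fragment:
        checked += 1
        if fraction_procedural_normalize(model, t) != fraction_conceptual_eval(model, t):
            disagreements.append(t)
    return checked, disagreements


def table4_membership(
    model: FractionModel, terms: Iterable[str | Term]
) -> dict[str, list[str]]:
    """Group fraction-language terms by their reduced-fraction class key."""
    out: dict[str, list[str]] = {}
    for item in terms:
        t = model.parse(item) if isinstance(item, str) else item
        v = fraction_procedural_normalize(model, t)
        key = v.render() if v.tag != "undefined" else "undefined"
        out.setdefault(key, []).append(render(t))
    return {k: sorted(v) for k, v in sorted(out.items())}


FRACTION_DIAGRAM_LITERALS = ("1/1", "1/2", "2/1", "2/2")


def fraction_diagram_setup(
    model: FractionModel | None = None,
    literals: Sequence[str] = FRACTION_DIAGRAM_LITERALS,
    depth: int = 2,
):
    """The fraction teaching diagram as a checkable setup.

    Source: the pizza domain (put_together / share_between / smaller_than)
    generated by the literal quantities; target: the fraction language over
    the same quantities; h is the identity on exact rationals.  Note the
    literal tokens 1/1 and 2/2 name the same quantity -- the kernel classes
    merge them, which is exactly the re-representation content.
    """
    from .hom_solver import extend_homomorphism, generator_map
    from .rerepresentation import DiagramSetup

    model = model or fraction_model()
    alpha0 = {v: model.literal_value(v) for v in literals}
    gens = tuple(sorted(set(alpha0.values())))
    bounds = Bounds(depth=depth, max_len=32, max_size=5000, max_apps=50_000)
    src = generate_closure(
        DomainSpec(model.context, model.pi, gens, "pizza"), bounds
    )
    tgt = generate_closure(
        DomainSpec(model.context, model.psi, gens, "number-line"), bounds
    )
    h = extend_homomorphism(
        src, tgt, model.F, generator_map({g: g for g in gens})
    )
    return DiagramSetup(model.F, h, dict(alpha0), depth=depth,
                        restrict_sorts=("rational",))


# -- error analysis ---------------------------------------------------------


def _mediant_eval(model: FractionModel, t: Term) -> Value:
    """The buggy "add tops, add bottoms" evaluator on written forms.

    Addition is the mediant of the *written* numerator/denominator pairs
    (2/4 + 1/3 -> 3/7); division and comparison are exact.  The final value
    is compared as an exact fraction.
    """

    def pair(u: Term) -> tuple[int, int] | None:
        if isinstance(u, Var):
            m, n = u.name.split("/")
            return int(m), int(n)
        parts = [pair(a) for a in u.args]
        if any(p is None for p in parts):
            return None
        (a, b), (c, d) = parts
        name = u.symbol.name
        if name == "plus":
            return (a + c, b + d)
        if name == "div":
            if c == 0:
                return None
            return (a * d, b * c)
        return None  # boolean-valued: handled below

    if isinstance(t, App) and t.symbol.name == "lt":
        left, right = (pair(a) for a in t.args)
        if left is None or right is None:
            return UNDEFINED
        from .contexts import boolean_value

        return boolean_value(Fraction(*left) < Fraction(*right))
    p = pair(t)
    if p is None or p[1] == 0:
        return UNDEFINED
    return rational_value(Fraction(*p))


@dataclass
class ErrorRuleReport:
    rule: str
    respects_kernel: bool
    witness: tuple[Term, Term] | None
    merged_classes: list[tuple[str, str]]  # pairs of class representatives conflated
    w: dict[str, str] | None  # class representative -> rule value (when factorable)


def error_rule_analysis(
    model: FractionModel, rule: str, fragment: Sequence[str | Term]
) -> ErrorRuleReport:
    """Does an alternative evaluator e factor through the quotient map?

    If e is constant on every pi_beta class of the fragment, the unique
    factor w = e . pi_beta^-1 exists and the report lists the class pairs w
    conflates (the "unduly identified" fraction concepts).  Otherwise two
    pi_beta-equivalent terms with different e-values witness that e does not
    respect the kernel at all.
    """
    if rule == "mediant":
        ev: Callable[[Term], Value] = lambda t: _mediant_eval(model, t)
    elif rule == "exact":
        ev = lambda t: fraction_procedural_normalize(model, t)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    terms = [model.parse(t) if isinstance(t, str) else t for t in fragment]
    by_class: dict[str, list[tuple[Term, Value]]] = {}
    for t in terms:
        v = fraction_procedural_normalize(model, t)
        if v.tag == "undefined":
            continue
        by_class.setdefault(v.render(), []).append((t, ev(t)))
    for key, members in by_class.items():
        first_t, first_v = members[0]
        for t, v in members[1:]:
            if v != first_v:
                return ErrorRuleReport(rule, False, (first_t, t), [], None)
    w = {key: members[0][1].render() for key, members in by_class.items()}
    by_value: dict[str, list[str]] = {}
    for key, val in w.items():
        by_value.setdefault(val, []).append(key)
    merged = []
    for val, keys in sorted(by_value.items()):
        keys = sorted(keys)
        for i in range(len(keys) - 1):
            merged.append((keys[i], keys[i + 1]))
    return ErrorRuleReport(rule, True, None, merged, w)


# -- rote-learner ablation ---------------------------------------------------


@dataclass
class RoteLearnerReport:
    classes_identical: bool
    n_classes: int
    proximity_conceptual: dict[str, str]  # term -> distance-to-one (exact)
    proximity_ablated: str


def rote_learner_ablation(
    model: FractionModel, fragment: Sequence[str | Term], queries: Sequence[str] = ()
) -> RoteLearnerReport:
    """Procedural-only learning: same classes, no notion of closeness.

    The quotient built from pi_beta alone equals the full model's quotient
    (both key classes by the reduced fraction), but proximity queries such as
    "is t close to 1?" require the conceptual route's magnitudes and come
    back unanswerable in the ablated mode.
    """
    terms = [model.parse(t) if isinstance(t, str) else t for t in fragment]
    proc = {}
    conc = {}
    for t in terms:
        pv = fraction_procedural_normalize(model, t)
        cv = fraction_conceptual_eval(model, t)
        if pv.tag == "undefined":
            continue
        proc.setdefault(pv.render(), []).append(render(t))
        conc.setdefault(cv.render(), []).append(render(t))
    identical = proc == conc
    prox = {}
    for q in queries:
        t = model.parse(q) if isinstance(q, str) else q
        v = fraction_conceptual_eval(model, t)
        if v.tag == "rational":
            d = abs(v.payload - 1)
            prox[render(t)] = f"{d.numerator}/{d.denominator}" if d.denominator != 1 else str(d.numerator)
    return RoteLearnerReport(
        identical, len(proc), prox, "no conceptual domain: proximity unavailable"
    )
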