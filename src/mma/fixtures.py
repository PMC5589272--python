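"""Seeded random domains and planted analogy problems, plus naive oracles.

The planted construction builds a source string domain, picks an injective
letter map, and pushes the generators through it.  Because the random schema
uses only the append and reversal operations -- both of which commute with
any letterwise injection -- the letter map is a genuine homomorphism by
construction, and the solver must recover exactly its values.

:func:`oracle_closure` is an independent reference for the closure operation:
a naive fixpoint iteration with no layering, no derivation index and no
application log.
"""

from __future__ import annotations

import random
import string
from dataclasses import dataclass
from itertools import product

from .contexts import Value, builtin_context, string_value
from .domain_closure import Bounds, DomainSpec, apply_operation, var_order
from .hom_solver import generator_map
from .problems import Modeling, ProblemSpec
from .term_core import App, Signature, Term, Var, identity_translation, term_key


@dataclass(frozen=True)
class GenParams:
    seed: int
    alphabet: int = 6  # generators drawn from the first k letters
    n_terms: int = 2
    term_depth: int = 3
    n_generators: int = 2
    bounds: Bounds = Bounds(depth=3, max_len=32, max_size=2000, max_apps=20_000)

    def __post_init__(self) -> None:
        if min(self.alphabet, self.n_terms, self.term_depth, self.n_generators) < 1:
            raise ValueError("generator parameters must be positive")


def _random_term(rng: random.Random, sig: Signature, depth: int, variables: list[str]) -> Term:
    if depth <= 1:
        return Var(rng.choice(variables))
    sym = sig[rng.choice(["lambda", "lambda", "sigma"])]  # bias toward binary
    args = tuple(_random_term(rng, sig, depth - 1, variables) for _ in range(sym.arity))
    return App(sym, args)


def random_domain(p: GenParams) -> DomainSpec:
    """A random string-domain spec: random schema, random short generators."""
    rng = random.Random(p.seed)
    ctx = builtin_context("strings")
    variables = ["x1", "x2"]
    terms: list[Term] = []
    while len(terms) < p.n_terms:
        t = _random_term(rng, ctx.signature, rng.randint(2, p.term_depth), variables)
        if isinstance(t, Var) or t in terms:
            continue
        terms.append(t)
    letters = string.ascii_lowercase[: p.alphabet]
    gens = []
    while len(gens) < p.n_generators:
        s = "".join(rng.choice(letters) for _ in range(rng.randint(1, 3)))
        v = string_value(s)
        if v not in gens:
            gens.append(v)
    return DomainSpec(ctx, tuple(sorted(terms, key=term_key)), tuple(gens), f"random[{p.seed}]")


def _letter_map(rng: random.Random, alphabet: int) -> dict[str, str]:
    src = list(string.ascii_lowercase[:alphabet])
    return dict(zip(src, rng.sample(src, k=alphabet)))


def _apply_letter_map(v: Value, lmap: dict[str, str]) -> Value:
    return string_value("".join(lmap[c] for c in v.payload))


def random_planted_problem(p: GenParams) -> tuple[ProblemSpec, dict[Value, Value]]:
    """A solvable problem with a planted homomorphism and its ground truth.

    The target is the image of the source under a random injective letter
    map; ground truth maps every bounded source element to its letter-mapped
    image.
    """
    from .domain_closure import generate_closure

    rng = random.Random(p.seed + 10_007)
    spec = random_domain(p)
    lmap = _letter_map(rng, p.alphabet)
    src = generate_closure(spec, p.bounds)
    elements = src.sorted_elements()
    ground_truth = {v: _apply_letter_map(v, lmap) for v in elements}
    tgt_spec = DomainSpec(
        spec.context,
        spec.pi,
        tuple(_apply_letter_map(g, lmap) for g in spec.generators),
        f"random-target[{p.seed}]",
    )
    # under hard caps the enumerated target subset need not be the image of
    # the enumerated source subset; query items are drawn so that the
    # membership preconditions hold by construction
    tgt = generate_closure(tgt_spec, p.bounds)
    candidates = [v for v in elements if ground_truth[v] in tgt] or elements
    item_a = rng.choice(candidates)
    item_b = rng.choice(elements)
    modeling = Modeling(
        "planted",
        spec,
        tgt_spec,
        identity_translation(list(spec.pi)),
        generator_map({g: _apply_letter_map(g, lmap) for g in spec.generators}),
    )
    problem = ProblemSpec(
        f"planted[{p.seed}]",
        [modeling],
        item_a.payload,
        item_b.payload,
        ground_truth[item_a].payload,
        p.bounds,
    )
    return problem, ground_truth


def corrupt_problem(problem: ProblemSpec, seed: int) -> ProblemSpec:
    """Flip one target generator image to a fresh string (mutation testing)."""
    rng = random.Random(seed)
    m = problem.modelings[0]
    pairs = dict(m.gmap.as_dict())
    victim = rng.choice(sorted(pairs))
    old = pairs[victim].payload
    pairs[victim] = string_value(old + rng.choice("zyx"))
    corrupted = Modeling(m.name + "-corrupted", m.source, m.target, m.translation,
                         generator_map(pairs))
    return ProblemSpec(
        problem.name + "-corrupted", [corrupted], problem.item_a, problem.item_b,
        problem.item_c, problem.bounds, problem.variables,
    )


def oracle_closure(spec: DomainSpec, bounds: Bounds) -> set[Value]:
    """Naive fixpoint closure: repeat until nothing new, no indexing.

    Independent of :func:`mma.domain_closure.generate_closure`; used as the
    reference in equivalence tests.  Only suitable for small bounds.
    """
    elements: set[Value] = set(spec.generators)
    for _ in range(bounds.depth):
        additions: set[Value] = set()
        for t in spec.pi:
            n = len(var_order(t))
            for combo in product(sorted(elements), repeat=n):
                out = apply_operation(spec.context, t, combo)
                if out.tag == "undefined":
                    continue
                if out.tag == "string" and out.key[0] > bounds.max_len:
                    continue
                if out not in elements:
                    additions.add(out)
        if not additions:
            break
        elements |= additions
        if len(elements) > bounds.max_size:
            break
    return elements
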