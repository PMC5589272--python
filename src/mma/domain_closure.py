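"""Bounded generated domains: closure of a generator set under term operations.

A domain spec is a context, a finite schema ``pi`` of terms, and a generator
set ``A0``.  The closure is the union of layers A_0, A_1, ... where layer i
applies every operation f_t (t in pi) to tuples of earlier elements.  The
true closure is typically infinite; :func:`generate_closure` enumerates it
breadth-first under explicit bounds and keeps a derivation index: every
distinct way an element was produced, which is what makes conflicting
derivations (and hence impossible analogies) detectable.

Bounds semantics: ``depth`` caps the number of layers, ``max_len`` the size of
a single element (string length / numerator+denominator digits etc.),
``max_size`` the number of elements, ``max_apps`` the number of operation
applications enumerated.  Hitting any cap sets ``truncated``; every
certificate downstream carries that flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

from .contexts import UNDEFINED, Context, Value
from .term_core import App, Term, Var, render, term_key, var_order


@dataclass(frozen=True)
class Bounds:
    depth: int = 4
    max_len: int = 64
    max_size: int = 20_000
    max_apps: int = 200_000
    max_derivations: int = 8

    def __post_init__(self) -> None:
        if min(self.depth, self.max_len, self.max_size, self.max_apps) < 0 or (
            self.max_size == 0 or self.max_apps == 0
        ):
            raise ValueError("bounds must be positive (depth may be zero)")


@dataclass(frozen=True)
class DomainSpec:
    context: Context
    pi: tuple[Term, ...]
    generators: tuple[Value, ...]
    name: str = ""

    def __post_init__(self) -> None:
        if not self.generators:
            raise ValueError("empty generator set")


@dataclass(frozen=True)
class Derivation:
    """gen(value), or step(t, children) with ``yields`` the recomputed value."""

    kind: str  # "gen" | "step"
    yields: Value
    term: Term | None = None
    children: tuple["Derivation", ...] = ()

    def render(self) -> str:
        if self.kind == "gen":
            return f"gen({self.yields.render()})"
        inner = ", ".join(c.yields.render() for c in self.children)
        return f"f[{render(self.term)}]({inner})"


@dataclass(frozen=True)
class Application:
    """One recorded operation application f_t(args) = result."""

    term: Term
    args: tuple[Value, ...]
    result: Value
    depth: int


@dataclass
class Domain:
    spec: DomainSpec
    bounds: Bounds
    elements: dict[Value, int]  # value -> first derivation depth
    derivations: dict[Value, list[Derivation]]
    applications: list[Application]
    truncated: bool = False
    caps_hit: bool = False  # max_size / max_apps stopped enumeration early
    undefined_count: int = 0

    @property
    def context(self) -> Context:
        return self.spec.context

    def sorted_elements(self) -> list[Value]:
        return sorted(self.elements)

    def __contains__(self, v: Value) -> bool:
        return v in self.elements


def _value_size(v: Value) -> int:
    if v.tag == "string":
        return v.key[0]
    if v.tag == "rational":
        return len(str(v.key[0])) + len(str(v.key[1]))
    if v.tag == "integer":
        return len(str(abs(v.key[0])))
    return 1


def evaluate_interpretation(
    context: Context, t: Term, assignment: Mapping[str, Value]
) -> Value:
    """The unique recursive extension of a variable assignment to a term.

    Kleene semantics: an undefined (or sort-incompatible) subresult makes the
    whole term undefined.
    """
    if isinstance(t, Var):
        try:
            return assignment[t.name]
        except KeyError:
            raise KeyError(f"assignment does not cover variable {t.name!r}") from None
    args = []
    for a in t.args:
        v = evaluate_interpretation(context, a, assignment)
        if v is UNDEFINED or v.tag == "undefined":
            return UNDEFINED
        args.append(v)
    if not context.applicable(t.symbol.name, args):
        return UNDEFINED
    return context.eval_symbol(t.symbol, args)


def apply_operation(context: Context, t: Term, args: Sequence[Value]) -> Value:
    """f_t(a1..an) with the canonical variable order of ``t``."""
    order = var_order(t)
    if len(args) != len(order):
        raise ValueError(
            f"operation f[{render(t)}] takes {len(order)} argument(s), got {len(args)}"
        )
    return evaluate_interpretation(context, t, dict(zip(order, args)))


def generate_closure(spec: DomainSpec, bounds: Bounds = Bounds()) -> Domain:
    """Breadth-first bounded closure with a full derivation index.

    Deterministic: layers are enumerated in canonical value order and schema
    terms in canonical term order, so element ordering, derivation lists and
    the application log are reproducible bit-for-bit.
    """
    elements: dict[Value, int] = {}
    derivations: dict[Value, list[Derivation]] = {}
    for g in spec.generators:
        if g not in elements:
            elements[g] = 0
            derivations[g] = [Derivation("gen", g)]
    applications: list[Application] = []
    seen_apps: set[tuple[Term, tuple[Value, ...]]] = set()
    truncated = False
    caps_hit = False
    undefined_count = 0
    pi = sorted(spec.pi, key=term_key)

    for d in range(1, bounds.depth + 1):
        known = sorted(elements)
        new_layer: dict[Value, int] = {}
        stop = False
        for t in pi:
            order = var_order(t)
            n = len(order)
            pools: list[list[Value]] = []
            usable = True
            for v in order:
                # sort-filter each argument position
                want = _var_sort(spec.context, t, v)
                pool = [u for u in known if want is None or u.tag == want]
                if not pool:
                    usable = False
                    break
                pools.append(pool)
            if not usable:
                continue
            for combo in product(*pools) if n else [()]:
                if n and max(elements[c] for c in combo) != d - 1:
                    continue  # already enumerated at an earlier layer
                if not n and d > 1:
                    continue  # constants belong to layer 1
                key = (t, combo)
                if key in seen_apps:
                    continue
                if len(applications) >= bounds.max_apps:
                    truncated = caps_hit = stop = True
                    break
                seen_apps.add(key)
                result = apply_operation(spec.context, t, combo)
                if result is UNDEFINED or result.tag == "undefined":
                    undefined_count += 1
                    continue
                if _value_size(result) > bounds.max_len:
                    truncated = True
                    continue
                applications.append(Application(t, combo, result, d))
                deriv = Derivation(
                    "step",
                    result,
                    t,
                    tuple(derivations[c][0] for c in combo),
                )
                if result not in elements and result not in new_layer:
                    new_layer[result] = d
                    derivations[result] = [deriv]
                    if len(elements) + len(new_layer) >= bounds.max_size:
                        truncated = caps_hit = stop = True
                        break
                elif len(derivations[result]) < bounds.max_derivations:
                    derivations[result].append(deriv)
            if stop:
                break
        elements.update(new_layer)
        if stop or not new_layer:
            if d < bounds.depth and stop:
                truncated = True
            break
    else:
        pass
    if bounds.depth > 0 and not truncated:
        # if the last processed layer still produced elements, the true
        # closure may extend beyond the depth bound
        last_layer = [v for v, dd in elements.items() if dd == bounds.depth]
        if last_layer:
            truncated = True
    return Domain(
        spec, bounds, elements, derivations, applications, truncated, caps_hit,
        undefined_count,
    )


def _var_sort(context: Context, t: Term, var: str) -> str | None:
    found: list[str] = []

    def walk(u: Term) -> None:
        if isinstance(u, Var):
            return
        arg_tags, _ = context.sorts[u.symbol.name]
        for i, a in enumerate(u.args):
            if isinstance(a, Var) and a.name == var:
                found.append(arg_tags[i])
            else:
                walk(a)

    walk(t)
    return found[0] if found else None


def find_derivations(d: Domain, v: Value) -> list[Derivation]:
    """All recorded derivations of ``v`` (generator derivation first)."""
    return list(d.derivations.get(v, []))
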