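"""Terms over signatures, substitution, term translations and term morphisms.

A *signature* is a finite set of function symbols with fixed arities.  Terms
are the usual syntax trees: a variable, or an application of an n-ary symbol
to n terms.  A finite set of terms ``pi`` acts as a schema of operations: each
term ``t`` with variables ``x1..xn`` (in canonical order) determines an n-ary
operation, either on a carrier (see :mod:`mma.domain_closure`) or on terms
themselves by substitution (the free symbolic domain ``Pi*(X)``).

A *term translation* ``F`` maps each schema term to a target term with exactly
the same variable set.  Its recursive extension ``F*`` to the free domain --
the *term morphism* -- is computed here by outermost pattern matching:
``F*(t[t1..tn]) = F(t)[F*(t1)..F*(tn)]`` with variables fixed.  Because a term
may decompose against the schema in more than one way, ``F*`` need not be
well defined; :func:`extend_term_morphism` checks every decomposition and
reports a witness when two of them disagree.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence


class TermError(ValueError):
    """Malformed term, signature violation or parse failure."""


@dataclass(frozen=True)
class Symbol:
    """An n-ary function symbol; 0-ary symbols are constants."""

    name: str
    arity: int

    def __post_init__(self) -> None:
        if self.arity < 0:
            raise TermError(f"negative arity for symbol {self.name!r}")


class Signature:
    """A set of function symbols with unique names."""

    def __init__(self, symbols: Iterable[Symbol] = ()) -> None:
        self._symbols: dict[str, Symbol] = {}
        for s in symbols:
            self.add(s)

    def add(self, symbol: Symbol) -> None:
        existing = self._symbols.get(symbol.name)
        if existing is not None and existing != symbol:
            raise TermError(f"symbol {symbol.name!r} redeclared with different arity")
        self._symbols[symbol.name] = symbol

    def __contains__(self, name: str) -> bool:
        return name in self._symbols

    def __getitem__(self, name: str) -> Symbol:
        try:
            return self._symbols[name]
        except KeyError:
            raise TermError(f"unknown symbol {name!r}") from None

    def symbols(self) -> list[Symbol]:
        return list(self._symbols.values())

    def __repr__(self) -> str:  # pragma: no cover
        inner = ", ".join(f"{s.name}/{s.arity}" for s in self._symbols.values())
        return f"Signature({inner})"


@dataclass(frozen=True)
class Var:
    name: str

    def __str__(self) -> str:
        return self.name


@dataclass(frozen=True)
class App:
    symbol: Symbol
    args: tuple["Term", ...] = ()

    def __post_init__(self) -> None:
        if len(self.args) != self.symbol.arity:
            raise TermError(
                f"symbol {self.symbol.name!r} has arity {self.symbol.arity}, "
                f"got {len(self.args)} arguments"
            )

    def __str__(self) -> str:
        return render(self)


Term = Var | App


def app(symbol: Symbol, *args: Term) -> App:
    return App(symbol, tuple(args))


def render(t: Term) -> str:
    """Canonical text: ``name(arg, arg)`` with single ``", "`` separators."""
    if isinstance(t, Var):
        return t.name
    if not t.args:
        return t.symbol.name
    return f"{t.symbol.name}({', '.join(render(a) for a in t.args)})"


def term_depth(t: Term) -> int:
    if isinstance(t, Var):
        return 1
    if not t.args:
        return 1
    return 1 + max(term_depth(a) for a in t.args)


def term_key(t: Term) -> tuple[int, str]:
    """Canonical ordering key: depth first, then rendered text."""
    return (term_depth(t), render(t))


_VAR_KEY_RE = re.compile(r"^([A-Za-z_]+?)(\d*)$")


def _name_key(name: str) -> tuple[str, int]:
    m = _VAR_KEY_RE.match(name)
    if m and m.group(2):
        return (m.group(1), int(m.group(2)))
    return (name, -1)


def variables_of(t: Term) -> frozenset[str]:
    if isinstance(t, Var):
        return frozenset((t.name,))
    out: set[str] = set()
    for a in t.args:
        out |= variables_of(a)
    return frozenset(out)


def var_order(t: Term) -> tuple[str, ...]:
    """Variables of ``t`` in canonical order (prefix, then numeric suffix).

    This is the argument order of the operation f_t determined by ``t``.
    """
    return tuple(sorted(variables_of(t), key=_name_key))


def substitute(t: Term, bindings: Mapping[str, Term]) -> Term:
    """Simultaneously replace every occurrence of each bound variable."""
    missing = variables_of(t) - set(bindings)
    if missing:
        raise TermError(f"missing binding for variable(s) {sorted(missing)}")
    return _substitute(t, bindings)


def _substitute(t: Term, bindings: Mapping[str, Term]) -> Term:
    if isinstance(t, Var):
        return bindings[t.name]
    return App(t.symbol, tuple(_substitute(a, bindings) for a in t.args))


# ---------------------------------------------------------------------------
# Parsing.  The grammar is:  term := VAR | NAME "(" term ("," term)* ")"
# ASCII aliases for the Greek letters of the string algebra are accepted and
# are also the canonical output: lambda (append), sigma (reverse),
# suc (letter successor), pre (letter predecessor).

_TOKEN_RE = re.compile(r"\s*(γ⁻¹|[λσγ]|[A-Za-z_][A-Za-z0-9_/]*|\d+/\d+|\d+|[(),])")

GREEK_ALIASES = {
    "λ": "lambda",
    "σ": "sigma",
    "γ": "suc",
    "γ⁻¹": "pre",
    "gamma": "suc",
    "gamma_inv": "pre",
}


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip() == "":
                break
            raise TermError(f"parse error at position {pos}: {text[pos:]!r}")
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


def parse_term(text: str, signature: Signature, variables: Iterable[str]) -> Term:
    """Parse canonical term text against a signature and a variable set."""
    varset = set(variables)
    tokens = _tokenize(text)
    if not tokens:
        raise TermError("empty term text")
    term, idx = _parse(tokens, 0, signature, varset)
    if idx != len(tokens):
        tok, at = tokens[idx]
        raise TermError(f"unexpected token {tok!r} at position {at}")
    return term


def _parse(
    tokens: list[tuple[str, int]], idx: int, signature: Signature, varset: set[str]
) -> tuple[Term, int]:
    if idx >= len(tokens):
        raise TermError("unexpected end of input (unbalanced parentheses?)")
    tok, at = tokens[idx]
    tok = GREEK_ALIASES.get(tok, tok)
    if tok in "(),":
        raise TermError(f"unexpected token {tok!r} at position {at}")
    if tok in varset:
        return Var(tok), idx + 1
    if tok not in signature:
        raise TermError(f"unknown symbol or variable {tok!r} at position {at}")
    sym = signature[tok]
    if idx + 1 >= len(tokens) or tokens[idx + 1][0] != "(":
        if sym.arity != 0:
            raise TermError(
                f"symbol {tok!r} (arity {sym.arity}) used without arguments at position {at}"
            )
        return App(sym, ()), idx + 1
    idx += 2  # skip NAME (
    args: list[Term] = []
    while True:
        arg, idx = _parse(tokens, idx, signature, varset)
        args.append(arg)
        if idx >= len(tokens):
            raise TermError("unbalanced parentheses: missing ')'")
        sep, sat = tokens[idx]
        idx += 1
        if sep == ")":
            break
        if sep != ",":
            raise TermError(f"expected ',' or ')' at position {sat}, got {sep!r}")
    if len(args) != sym.arity:
        raise TermError(
            f"arity mismatch at position {at}: {tok!r} takes {sym.arity} "
            f"argument(s), got {len(args)}"
        )
    return App(sym, tuple(args)), idx


# ---------------------------------------------------------------------------
# Term translations and term morphisms.


class TranslationError(TermError):
    pass


@dataclass(frozen=True)
class TermTranslation:
    """A variable-preserving map from a finite schema Pi to a schema Psi."""

    pairs: tuple[tuple[Term, Term], ...]
    _map: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_map", {s: i for s, i in self.pairs})

    @property
    def domain(self) -> tuple[Term, ...]:
        return tuple(s for s, _ in self.pairs)

    @property
    def image(self) -> tuple[Term, ...]:
        return tuple(i for _, i in self.pairs)

    def apply(self, t: Term) -> Term:
        try:
            return self._map[t]
        except KeyError:
            raise TranslationError(f"term {render(t)} not in translation domain") from None

    def __call__(self, t: Term) -> Term:
        return self.apply(t)

    def inverse(self) -> "TermTranslation":
        """The inverse translation; requires the map to be injective."""
        seen: dict[Term, Term] = {}
        for s, i in self.pairs:
            if i in seen:
                raise TranslationError(
                    f"translation not injective: {render(seen[i])} and {render(s)} "
                    f"both map to {render(i)}"
                )
            seen[i] = s
        return TermTranslation(tuple((i, s) for s, i in self.pairs))


def make_translation(pairs: Sequence[tuple[Term, Term]]) -> TermTranslation:
    """Validate and build a term translation.

    Rejects any pair whose source and image have different variable sets.
    """
    if not pairs:
        raise TranslationError("translation needs at least one pair")
    sources = [s for s, _ in pairs]
    if len(set(sources)) != len(sources):
        raise TranslationError("duplicate source terms in translation")
    for s, i in pairs:
        if variables_of(s) != variables_of(i):
            raise TranslationError(
                f"pair ({render(s)} -> {render(i)}) does not preserve variables: "
                f"{sorted(variables_of(s))} vs {sorted(variables_of(i))}"
            )
    return TermTranslation(tuple(pairs))


def identity_translation(pi: Sequence[Term]) -> TermTranslation:
    return make_translation([(t, t) for t in pi])


def match(pattern: Term, t: Term) -> dict[str, Term] | None:
    """Nonlinear first-order match of ``t`` against ``pattern``.

    Repeated pattern variables must bind syntactically equal subterms.
    Returns the binding map, or None when there is no match.
    """
    bindings: dict[str, Term] = {}
    if _match(pattern, t, bindings):
        return bindings
    return None


def _match(pattern: Term, t: Term, bindings: dict[str, Term]) -> bool:
    if isinstance(pattern, Var):
        bound = bindings.get(pattern.name)
        if bound is None:
            bindings[pattern.name] = t
            return True
        return bound == t
    if isinstance(t, Var) or t.symbol != pattern.symbol:
        return False
    return all(_match(p, a, bindings) for p, a in zip(pattern.args, t.args))


class UndecomposableTermError(TermError):
    """A fragment term matches no schema term and is not a variable."""


@dataclass
class TermMorphismTable:
    """F* computed on a bounded fragment of the free domain.

    ``status`` is "consistent" when every decomposition of every fragment term
    yields the same image; otherwise "inconsistent" and ``witness`` is a term
    with two decompositions whose images differ (stored in ``witness_images``).
    """

    base: TermTranslation
    fragment_map: dict[Term, Term]
    status: str = "consistent"
    witness: Term | None = None
    witness_images: tuple[Term, Term] | None = None

    def apply(self, t: Term) -> Term:
        return self.fragment_map[t]

    def __call__(self, t: Term) -> Term:
        return self.apply(t)


def extend_term_morphism(
    F: TermTranslation, fragment: Iterable[Term]
) -> TermMorphismTable:
    """Extend ``F`` to ``F*`` over ``fragment`` by outermost decomposition.

    For each fragment term, every decomposition ``t[t1..tn]`` with ``t`` in the
    schema is found by nonlinear pattern matching, and the recursion
    ``F*(t[t1..tn]) = F(t)[F*(t1)..F*(tn)]`` is applied; variables are fixed.
    All decompositions must agree, else the table is inconsistent with a
    witness.  Raises :class:`UndecomposableTermError` for a non-variable term
    matching no schema term.
    """
    table = TermMorphismTable(base=F, fragment_map={})
    _FAIL = object()
    cache: dict[Term, object] = {}

    def fstar(t: Term):
        """Image of t, or _FAIL when t is not generated by the schema.

        A candidate decomposition only counts when every bound subterm is
        itself decomposable (i.e. genuinely lies in the free domain).
        """
        if t in cache:
            return cache[t]
        if isinstance(t, Var):
            cache[t] = t
            return t
        cache[t] = _FAIL  # provisional: also guards against cyclic matching
        images: list[Term] = []
        for src in F.domain:
            b = match(src, t)
            if b is None:
                continue
            sub_images = {v: fstar(sub) for v, sub in b.items()}
            if any(i is _FAIL for i in sub_images.values()):
                continue
            img = substitute(F.apply(src), sub_images)
            if img not in images:
                images.append(img)
        if not images:
            return _FAIL
        if len(images) > 1 and table.status == "consistent":
            table.status = "inconsistent"
            table.witness = t
            table.witness_images = (images[0], images[1])
        cache[t] = images[0]
        return images[0]

    for t in sorted(fragment, key=term_key):
        img = fstar(t)
        if img is _FAIL:
            raise UndecomposableTermError(
                f"term {render(t)} is not generated by the schema"
            )
        table.fragment_map[t] = img
    return table


# ---------------------------------------------------------------------------
# The free symbolic domain Pi*(X), bounded.


def free_fragment(
    pi: Sequence[Term],
    variables: Sequence[str],
    depth: int,
    max_terms: int = 50_000,
    sort_of: "SortMap | None" = None,
) -> list[Term]:
    """Enumerate the free domain Pi*(X) up to substitution depth ``depth``.

    Layer 0 is the variable set; layer k+1 adds every substitution of layer
    <=k terms into a schema term.  When ``sort_of`` is given, only
    sort-correct substitutions are generated (see :class:`SortMap`).
    """
    elements: dict[Term, int] = {Var(v): 0 for v in variables}
    for d in range(1, depth + 1):
        known = sorted(elements, key=term_key)
        new: list[Term] = []
        for t in pi:
            order = var_order(t)
            pools: list[list[Term]] = []
            ok = True
            for v in order:
                want = sort_of.var_sort(t, v) if sort_of else None
                pool = [
                    u
                    for u in known
                    if want is None or sort_of is None or sort_of.term_sort(u) == want
                ]
                if not pool:
                    ok = False
                    break
                pools.append(pool)
            if not ok:
                continue
            for combo in _product(pools):
                if max(
                    (elements[c] for c in combo), default=0
                ) != d - 1 and order:
                    continue  # tuple already generated at an earlier layer
                term = substitute(t, dict(zip(order, combo))) if order else t
                if term not in elements:
                    elements[term] = d
                    new.append(term)
                    if len(elements) >= max_terms:
                        return sorted(elements, key=term_key)
        if not new and d > 1:
            break
    return sorted(elements, key=term_key)


def _product(pools: list[list[Term]]):
    if not pools:
        yield ()
        return
    from itertools import product

    yield from product(*pools)


class SortMap:
    """Sort (tag) discipline for typed fragments.

    ``var_sorts`` assigns a sort to each free variable; ``symbol_sorts`` maps
    each symbol name to ``(arg_sorts, result_sort)``.  Schema variables take
    the sort of the position they occupy.
    """

    def __init__(
        self,
        var_sorts: Mapping[str, str],
        symbol_sorts: Mapping[str, tuple[tuple[str, ...], str]],
    ) -> None:
        self.var_sorts = dict(var_sorts)
        self.symbol_sorts = dict(symbol_sorts)

    def term_sort(self, t: Term) -> str | None:
        if isinstance(t, Var):
            return self.var_sorts.get(t.name)
        info = self.symbol_sorts.get(t.symbol.name)
        return info[1] if info else None

    def var_sort(self, schema_term: Term, var: str) -> str | None:
        """The sort demanded of ``var`` by its position(s) in ``schema_term``."""
        found: list[str] = []
        self._positions(schema_term, var, found)
        return found[0] if found else None

    def _positions(self, t: Term, var: str, found: list[str]) -> None:
        if isinstance(t, Var):
            return
        info = self.symbol_sorts.get(t.symbol.name)
        for i, a in enumerate(t.args):
            if isinstance(a, Var) and a.name == var and info:
                found.append(info[0][i])
            else:
                self._positions(a, var, found)
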