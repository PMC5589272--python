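"""Concrete carriers (K-algebras) used throughout the kit.

A :class:`Context` packages a signature with one partial operation per
function symbol, acting on tagged :class:`Value` objects.  Operations never
raise on out-of-range inputs: they return the distinguished ``UNDEFINED``
outcome, and undefinedness propagates (Kleene semantics).  Passing a value of
the wrong sort or the wrong number of arguments is a *contract* error --
a bug in the caller -- and raises :class:`ContractError` instead.

Built-in contexts:

``strings``
    nonempty lowercase strings with ``lambda`` (append) and ``sigma``
    (reversal).
``strings_succ``
    additionally ``suc``/``pre``: letterwise alphabet successor/predecessor
    with wraparound (suc(z) = a, pre(a) = z).
``rationals``
    exact positive rationals with ``put_together``/``plus`` (+),
    ``share_between``/``div`` (exact division, undefined at 0) and
    ``smaller_than``/``lt`` (boolean <).
``integers``
    integers with ``plus``.
``board``
    ``n`` boxes, linear or circular: ``go_to_right`` (partial at the last box
    when linear, wrapping when circular), ``stroll_distance`` (the box |i-j|
    steps in; undefined at 0 or off-board), ``left_of`` and ``tie``
    (boolean).  Circular boards sit evenly on a unit circle and compare
    left/right by the signed angular step (strictly between 0 and half a
    turn); stroll distance is undefined there because no box encodes a chord.
``persons``
    a parent chain with unary parent/child maps and boolean kinship
    relations; symbol names come in a paternal (father/son) and a maternal
    (mother/daughter) lexicon.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass
from fractions import Fraction
from typing import Any, Callable, Mapping, Sequence

from .term_core import Signature, Symbol


class ContractError(TypeError):
    """Wrong sort or arity handed to an operation (distinct from undefined)."""


@dataclass(frozen=True, order=True)
class Value:
    """A tagged carrier element.  Ordering is canonical (tag, then payload key)."""

    tag: str
    key: tuple = ()

    @property
    def payload(self) -> Any:
        if self.tag == "string":
            return self.key[1]
        if self.tag == "rational":
            return Fraction(self.key[0], self.key[1])
        if self.tag in ("integer", "box"):
            return self.key[0]
        if self.tag == "person":
            return self.key[0]
        if self.tag == "boolean":
            return bool(self.key[0])
        return self.key

    def __repr__(self) -> str:
        return f"<{self.tag}:{self.render()}>"

    def render(self) -> str:
        if self.tag == "string":
            return self.key[1]
        if self.tag == "rational":
            n, d = self.key
            return f"{n}" if d == 1 else f"{n}/{d}"
        if self.tag == "box":
            return f"box{self.key[0]}"
        if self.tag == "boolean":
            return "TRUE" if self.key[0] else "FALSE"
        return str(self.key[0])


UNDEFINED = Value("undefined", ())


def string_value(s: str) -> Value:
    if not s or any(c not in string.ascii_lowercase for c in s):
        raise ContractError(f"string values are nonempty over a-z, got {s!r}")
    return Value("string", (len(s), s))  # shortlex canonical order


def rational_value(x: Fraction | int) -> Value:
    f = Fraction(x)
    return Value("rational", (f.numerator, f.denominator))


def integer_value(n: int) -> Value:
    return Value("integer", (n,))


def box_value(i: int) -> Value:
    return Value("box", (i,))


def person_value(name: str) -> Value:
    return Value("person", (name,))


def boolean_value(b: bool) -> Value:
    return Value("boolean", (1 if b else 0,))


TRUE = boolean_value(True)
FALSE = boolean_value(False)


@dataclass
class Context:
    """A signature plus one partial operation per symbol, with sort info."""

    name: str
    signature: Signature
    ops: dict[str, Callable[..., Value]]
    sorts: dict[str, tuple[tuple[str, ...], str]]
    carrier_tag: str

    def eval_symbol(self, symbol: Symbol | str, args: Sequence[Value]) -> Value:
        name = symbol if isinstance(symbol, str) else symbol.name
        sym = self.signature[name]
        if len(args) != sym.arity:
            raise ContractError(
                f"{name} takes {sym.arity} argument(s), got {len(args)}"
            )
        if any(a is UNDEFINED or a.tag == "undefined" for a in args):
            return UNDEFINED
        arg_tags, _ = self.sorts[name]
        for a, want in zip(args, arg_tags):
            if a.tag != want:
                raise ContractError(
                    f"{name} expects a {want} argument, got {a.tag} {a.render()}"
                )
        return self.ops[name](*args)

    def applicable(self, symbol_name: str, args: Sequence[Value]) -> bool:
        """Sort compatibility check (used by closure machinery to skip, not raise)."""
        arg_tags, _ = self.sorts[symbol_name]
        return len(args) == len(arg_tags) and all(
            a.tag == t for a, t in zip(args, arg_tags)
        )

    def result_sort(self, symbol_name: str) -> str:
        return self.sorts[symbol_name][1]


def eval_symbol(c: Context, f: Symbol | str, args: Sequence[Value]) -> Value:
    return c.eval_symbol(f, args)


# ---------------------------------------------------------------------------
# Builders.

_ALPHA = string.ascii_lowercase


def _letter_shift(s: str, delta: int) -> str:
    return "".join(_ALPHA[(_ALPHA.index(c) + delta) % 26] for c in s)


def _strings_context(with_succ: bool) -> Context:
    sig = Signature([Symbol("lambda", 2), Symbol("sigma", 1)])
    ops: dict[str, Callable[..., Value]] = {
        "lambda": lambda a, b: string_value(a.payload + b.payload),
        "sigma": lambda a: string_value(a.payload[::-1]),
    }
    sorts = {
        "lambda": (("string", "string"), "string"),
        "sigma": (("string",), "string"),
    }
    name = "strings"
    if with_succ:
        name = "strings_succ"
        sig.add(Symbol("suc", 1))
        sig.add(Symbol("pre", 1))
        ops["suc"] = lambda a: string_value(_letter_shift(a.payload, 1))
        ops["pre"] = lambda a: string_value(_letter_shift(a.payload, -1))
        sorts["suc"] = (("string",), "string")
        sorts["pre"] = (("string",), "string")
    return Context(name, sig, ops, sorts, "string")


def _rationals_context() -> Context:
    def plus(a: Value, b: Value) -> Value:
        return rational_value(a.payload + b.payload)

    def div(a: Value, b: Value) -> Value:
        if b.payload == 0:
            return UNDEFINED
        return rational_value(a.payload / b.payload)

    def lt(a: Value, b: Value) -> Value:
        return boolean_value(a.payload < b.payload)

    sig = Signature(
        [
            Symbol("put_together", 2),
            Symbol("share_between", 2),
            Symbol("smaller_than", 2),
            Symbol("plus", 2),
            Symbol("div", 2),
            Symbol("lt", 2),
        ]
    )
    rr = ("rational", "rational")
    ops = {
        "put_together": plus,
        "plus": plus,
        "share_between": div,
        "div": div,
        "smaller_than": lt,
        "lt": lt,
    }
    sorts = {
        "put_together": (rr, "rational"),
        "plus": (rr, "rational"),
        "share_between": (rr, "rational"),
        "div": (rr, "rational"),
        "smaller_than": (rr, "boolean"),
        "lt": (rr, "boolean"),
    }
    return Context("rationals", sig, ops, sorts, "rational")


def _integers_context() -> Context:
    sig = Signature([Symbol("plus", 2)])
    ops = {"plus": lambda a, b: integer_value(a.payload + b.payload)}
    sorts = {"plus": (("integer", "integer"), "integer")}
    return Context("integers", sig, ops, sorts, "integer")


def _board_context(n: int, shape: str) -> Context:
    if n < 1:
        raise ContractError("board needs at least one box")
    if shape not in ("linear", "circular"):
        raise ContractError(f"unknown board shape {shape!r}")

    def go_to_right(a: Value) -> Value:
        i = a.payload
        if i == n:
            return box_value(1) if shape == "circular" else UNDEFINED
        return box_value(i + 1)

    def stroll_distance(a: Value, b: Value) -> Value:
        if shape == "circular":
            return UNDEFINED  # chord lengths are not boxes
        d = abs(a.payload - b.payload)
        return box_value(d) if 1 <= d <= n else UNDEFINED

    def left_of(a: Value, b: Value) -> Value:
        if shape == "linear":
            return boolean_value(a.payload < b.payload)
        step = (b.payload - a.payload) % n
        return boolean_value(0 < step < n / 2)

    def tie(a: Value, b: Value) -> Value:
        return boolean_value(a.payload == b.payload)

    sig = Signature(
        [
            Symbol("go_to_right", 1),
            Symbol("stroll_distance", 2),
            Symbol("left_of", 2),
            Symbol("tie", 2),
        ]
    )
    bb = ("box", "box")
    ops = {
        "go_to_right": go_to_right,
        "stroll_distance": stroll_distance,
        "left_of": left_of,
        "tie": tie,
    }
    sorts = {
        "go_to_right": (("box",), "box"),
        "stroll_distance": (bb, "box"),
        "left_of": (bb, "boolean"),
        "tie": (bb, "boolean"),
    }
    ctx = Context(f"board({n},{shape})", sig, ops, sorts, "box")
    ctx.n_boxes = n  # type: ignore[attr-defined]
    ctx.shape = shape  # type: ignore[attr-defined]
    return ctx


def board_positions(n: int, shape: str) -> dict[int, tuple[float, float]]:
    """Box coordinates: collinear unit-spaced, or evenly on a unit circle."""
    if shape == "linear":
        return {i: (float(i), 0.0) for i in range(1, n + 1)}
    return {
        i: (
            math.cos(2 * math.pi * (i - 1) / n),
            math.sin(2 * math.pi * (i - 1) / n),
        )
        for i in range(1, n + 1)
    }


def _numbers_context(n: int) -> Context:
    """Numbers 1..n with successor, |X-Y|, < and = (partial at the edges).

    The carrier is restricted to 1..n so that successor(n) and a zero
    difference are undefined, mirroring the partial spatial operations of the
    matching board.
    """

    def inside(k: int) -> Value:
        return integer_value(k) if 1 <= k <= n else UNDEFINED

    sig = Signature(
        [Symbol("successor", 1), Symbol("abs_diff", 2), Symbol("lt", 2), Symbol("eq", 2)]
    )
    ii = ("integer", "integer")
    ops = {
        "successor": lambda a: inside(a.payload + 1),
        "abs_diff": lambda a, b: inside(abs(a.payload - b.payload)),
        "lt": lambda a, b: boolean_value(a.payload < b.payload),
        "eq": lambda a, b: boolean_value(a.payload == b.payload),
    }
    sorts = {
        "successor": (("integer",), "integer"),
        "abs_diff": (ii, "integer"),
        "lt": (ii, "boolean"),
        "eq": (ii, "boolean"),
    }
    return Context(f"numbers({n})", sig, ops, sorts, "integer")


_PATERNAL = ("father", "son", "is_father_of", "is_son_of")
_MATERNAL = ("mother", "daughter", "is_mother_of", "is_daughter_of")


def _persons_context(parents: Sequence[tuple[str, str]], lexicon: str) -> Context:
    """A chain of persons; ``parents`` lists (parent, child) pairs."""
    names = _PATERNAL if lexicon == "paternal" else _MATERNAL
    parent_sym, child_sym, is_parent_sym, is_child_sym = names
    parent_of = {child: parent for parent, child in parents}
    child_of = {parent: child for parent, child in parents}
    if len(parent_of) != len(parents) or len(child_of) != len(parents):
        raise ContractError("pedigree must be a simple chain (one child per parent)")

    def parent(a: Value) -> Value:
        p = parent_of.get(a.payload)
        return person_value(p) if p else UNDEFINED

    def child(a: Value) -> Value:
        c = child_of.get(a.payload)
        return person_value(c) if c else UNDEFINED

    def is_parent(a: Value, b: Value) -> Value:
        return boolean_value(parent_of.get(b.payload) == a.payload)

    def is_child(a: Value, b: Value) -> Value:
        return boolean_value(parent_of.get(a.payload) == b.payload)

    sig = Signature(
        [
            Symbol(parent_sym, 1),
            Symbol(child_sym, 1),
            Symbol(is_parent_sym, 2),
            Symbol(is_child_sym, 2),
            Symbol("TRUE", 0),
            Symbol("FALSE", 0),
        ]
    )
    pp = ("person", "person")
    ops = {
        parent_sym: parent,
        child_sym: child,
        is_parent_sym: is_parent,
        is_child_sym: is_child,
        "TRUE": lambda: TRUE,
        "FALSE": lambda: FALSE,
    }
    sorts = {
        parent_sym: (("person",), "person"),
        child_sym: (("person",), "person"),
        is_parent_sym: (pp, "boolean"),
        is_child_sym: (pp, "boolean"),
        "TRUE": ((), "boolean"),
        "FALSE": ((), "boolean"),
    }
    return Context(f"persons({lexicon})", sig, ops, sorts, "person")


def builtin_context(name: str, **params: Any) -> Context:
    """Build a named context.  See the module docstring for the catalogue."""
    if name == "strings":
        return _strings_context(with_succ=False)
    if name == "strings_succ":
        return _strings_context(with_succ=True)
    if name == "rationals":
        return _rationals_context()
    if name == "integers":
        return _integers_context()
    if name == "board":
        return _board_context(params.get("n", 10), params.get("shape", "linear"))
    if name == "numbers":
        return _numbers_context(params.get("n", 10))
    if name == "persons":
        return _persons_context(params["parents"], params.get("lexicon", "paternal"))
    raise ContractError(f"unknown context {name!r}")


def parse_value(text: str, context: Context) -> Value:
    """Read a carrier value from problem-file text."""
    tag = context.carrier_tag
    if tag == "string":
        return string_value(text)
    if tag == "rational":
        if "/" in text:
            n, d = text.split("/")
            return rational_value(Fraction(int(n), int(d)))
        return rational_value(int(text))
    if tag == "integer":
        return integer_value(int(text))
    if tag == "box":
        return box_value(int(text.removeprefix("box")))
    if tag == "person":
        return person_value(text)
    raise ContractError(f"cannot parse {text!r} for carrier {tag!r}")
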