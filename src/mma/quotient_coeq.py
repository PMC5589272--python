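"""Kernel partitions, quotient domains and the coequalizer factorization.

An :class:`Interpretation` is a total map from a bounded fragment (of carrier
values, or of terms of a free symbolic domain) into some carrier.  Its
*kernel partition* groups fragment elements by image -- the fibers.  A
:class:`QuotientDomain` equips those classes with induced operations
``f_t([a1]..[an]) = [f_t(a1..an)]``; rather than assuming well-definedness,
:func:`build_quotient` re-evaluates every operation on every member tuple
within the fragment and reports a witness when the result class depends on
the choice of representatives.

:func:`coequalizer_factor` is the universal property made executable: a map
``z`` that is constant on every class factors uniquely through the quotient
map as ``z = u . pi``; otherwise the violating class and two members with
different z-images are returned (as a result value, not an exception).

:func:`first_isomorphism` verifies that a surjective structure-preserving
interpretation induces an isomorphism between its kernel quotient and its
image -- the first isomorphism theorem at bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Any, Callable, Hashable, Iterable, Mapping, Sequence

from .contexts import UNDEFINED, Context, Value
from .domain_closure import Domain, apply_operation
from .term_core import (
    SortMap,
    Term,
    TermTranslation,
    Var,
    free_fragment,
    identity_translation,
    render,
    substitute,
    term_depth,
    term_key,
    var_order,
    variables_of,
)

Element = Any  # a carrier Value or a Term


def element_key(e: Element):
    """Canonical ordering key: min depth first, then text."""
    if isinstance(e, Value):
        return (1, "", e)
    return (term_depth(e), render(e), None)


def render_element(e: Element) -> str:
    return e.render() if isinstance(e, Value) else render(e)


# ---------------------------------------------------------------------------
# Fragment bases: anything with elements, a schema and a partial apply.


class FragmentBase:
    """A bounded carrier: elements, schema terms, and a partial apply."""

    elements: list[Element]
    pi: tuple[Term, ...]

    def apply(self, t: Term, args: Sequence[Element]) -> Element | None:
        raise NotImplementedError


class DomainBase(FragmentBase):
    """A generated domain viewed as a fragment base."""

    def __init__(self, domain: Domain) -> None:
        from .domain_closure import _var_sort

        self.domain = domain
        self.elements = domain.sorted_elements()
        self.pi = tuple(sorted(domain.spec.pi, key=term_key))
        self._set = set(self.elements)
        ctx = domain.context
        self._arg_sorts = {
            t: tuple(_var_sort(ctx, t, v) for v in var_order(t)) for t in self.pi
        }

    def apply(self, t, args):
        if any(not isinstance(a, Value) or a not in self._set for a in args):
            return None
        sorts = self._arg_sorts.get(t)
        if sorts is not None:
            for a, want in zip(args, sorts):
                if want is not None and a.tag != want:
                    return None
        out = apply_operation(self.domain.context, t, args)
        if out is UNDEFINED or out.tag == "undefined":
            return None
        return out if out in self._set else None


class SymbolicBase(FragmentBase):
    """A depth-bounded fragment of the free symbolic domain Pi*(X)."""

    def __init__(
        self,
        pi: Sequence[Term],
        variables: Sequence[str],
        depth: int,
        sort_of: SortMap | None = None,
        elements: Sequence[Term] | None = None,
    ) -> None:
        self.pi = tuple(sorted(pi, key=term_key))
        self.variables = tuple(variables)
        self.depth = depth
        self.sort_of = sort_of
        if elements is None:
            elements = free_fragment(self.pi, variables, depth, sort_of=sort_of)
        self.elements = sorted(elements, key=term_key)
        self._set = set(self.elements)
        self._depths = {e: term_depth(e) for e in self.elements}
        self._max_depth = max(self._depths.values(), default=0)
        # per schema term: depth of each variable position and of rigid leaves,
        # so the depth of a substitution instance is computable without
        # building it
        self._schema_profile: dict[Term, tuple[int, dict[str, int]]] = {}
        for t in self.pi:
            var_depth: dict[str, int] = {}
            static = [1]

            def walk(u: Term, d: int) -> None:
                if isinstance(u, Var):
                    var_depth[u.name] = max(var_depth.get(u.name, 0), d)
                    return
                if not u.args:
                    static[0] = max(static[0], d)
                for a in u.args:
                    walk(a, d + 1)

            walk(t, 1)
            self._schema_profile[t] = (static[0], var_depth)

    def restrict(self, keep: Callable[[Term], bool]) -> "SymbolicBase":
        return SymbolicBase(
            self.pi,
            self.variables,
            self.depth,
            self.sort_of,
            [e for e in self.elements if keep(e)],
        )

    def apply(self, t, args):
        order = var_order(t)
        if len(args) != len(order):
            return None
        profile = self._schema_profile.get(t)
        if profile is not None:
            static, var_depth = profile
            try:
                result_depth = max(
                    [static]
                    + [var_depth[v] + self._depths[a] - 1 for v, a in zip(order, args)]
                )
            except KeyError:
                return None
            if result_depth > self._max_depth:
                return None  # provably outside the bounded fragment
        out = substitute(t, dict(zip(order, args)))
        return out if out in self._set else None


class MapBase(FragmentBase):
    """A finite carrier fragment given by an explicit apply function."""

    def __init__(
        self,
        elements: Iterable[Element],
        pi: Sequence[Term],
        apply_fn: Callable[[Term, Sequence[Element]], Element | None],
    ) -> None:
        self.elements = sorted(elements, key=element_key)
        self.pi = tuple(sorted(pi, key=term_key))
        self._apply = apply_fn
        self._set = set(self.elements)

    def apply(self, t, args):
        out = self._apply(t, args)
        if out is None or (isinstance(out, Value) and out.tag == "undefined"):
            return None
        return out if out in self._set else None


# ---------------------------------------------------------------------------
# Interpretations, partitions, quotients.


@dataclass
class Interpretation:
    """A named total map from a fragment into a carrier (alpha, beta, ...)."""

    name: str
    fragment: list[Element]
    map: dict[Element, Value]

    def __post_init__(self) -> None:
        missing = [e for e in self.fragment if e not in self.map]
        if missing:
            raise ValueError(
                f"interpretation {self.name!r} not total: no image for "
                f"{render_element(missing[0])}"
            )

    def __call__(self, e: Element) -> Value:
        return self.map[e]


@dataclass
class Partition:
    classes: list[list[Element]]  # each sorted; classes sorted by representative

    def __post_init__(self) -> None:
        seen: set = set()
        for cls in self.classes:
            if not cls:
                raise ValueError("empty class in partition")
            for e in cls:
                if e in seen:
                    raise ValueError(f"element {render_element(e)} in two classes")
                seen.add(e)
        self._index = {e: i for i, cls in enumerate(self.classes) for e in cls}

    @property
    def representatives(self) -> list[Element]:
        return [cls[0] for cls in self.classes]

    def class_of(self, e: Element) -> int:
        return self._index[e]

    def members(self, i: int) -> list[Element]:
        return self.classes[i]

    def __len__(self) -> int:
        return len(self.classes)

    def covers(self, elements: Iterable[Element]) -> bool:
        return all(e in self._index for e in elements)


def kernel_partition(i: Interpretation) -> Partition:
    """The fibers of an interpretation, canonically ordered."""
    if not i.fragment:
        raise ValueError("empty fragment")
    fibers: dict[Value, list[Element]] = {}
    for e in i.fragment:
        fibers.setdefault(i.map[e], []).append(e)
    classes = [sorted(v, key=element_key) for v in fibers.values()]
    classes.sort(key=lambda cls: element_key(cls[0]))
    return Partition(classes)


@dataclass
class QuotientDomain:
    base: FragmentBase
    partition: Partition
    ops: dict[tuple[Term, tuple[int, ...]], int]
    well_defined: bool
    witness: tuple | None = None  # (t, args_a, args_b, class_a, class_b)
    checked: int = 0

    def project(self, e: Element) -> int:
        """The quotient map pi, as a class index."""
        return self.partition.class_of(e)

    def apply_class(self, t: Term, class_indices: Sequence[int]) -> int | None:
        return self.ops.get((t, tuple(class_indices)))

    def class_listing(self) -> list[list[str]]:
        return [[render_element(e) for e in cls] for cls in self.partition.classes]


def build_quotient(
    base: FragmentBase, partition: Partition, max_checks: int = 200_000
) -> QuotientDomain:
    """Induced class-level operations, with exhaustive well-definedness checks.

    Every member tuple (within the fragment, up to ``max_checks``) is
    re-evaluated; tuples whose result escapes the fragment are skipped, which
    is the bounded reading of the infinite quotient.
    """
    if not partition.covers(base.elements):
        raise ValueError("partition does not cover the base elements")
    ops: dict[tuple[Term, tuple[int, ...]], int] = {}
    witness = None
    checked = 0
    for t in base.pi:
        n = len(var_order(t))
        for combo in product(base.elements, repeat=n):
            if checked >= max_checks:
                break
            checked += 1
            out = base.apply(t, combo)
            if out is None:
                continue
            key = (t, tuple(partition.class_of(a) for a in combo))
            res = partition.class_of(out)
            if key in ops:
                if ops[key] != res and witness is None:
                    witness = (t, combo, ops[key], res)
            else:
                ops[key] = res
    return QuotientDomain(base, partition, ops, witness is None, witness, checked)


@dataclass
class FactorizationResult:
    u: dict[int, Value] | None
    unique: bool
    commutes: bool
    violation: tuple | None = None  # (class index, member_a, member_b, za, zb)

    @property
    def ok(self) -> bool:
        return self.commutes and self.violation is None


def coequalizer_factor(q: QuotientDomain, z: Interpretation) -> FactorizationResult:
    """Factor ``z`` through the quotient map: z = u . pi, u unique.

    Exists iff z is constant on every class; otherwise the violating class
    and two members with different z-images are reported.
    """
    u: dict[int, Value] = {}
    for i, cls in enumerate(q.partition.classes):
        images = [(e, z.map[e]) for e in cls]
        first_e, first_v = images[0]
        for e, v in images[1:]:
            if v != first_v:
                return FactorizationResult(
                    None, False, False, (i, first_e, e, first_v, v)
                )
        u[i] = first_v
    return FactorizationResult(u, True, True)


@dataclass
class IsoTheoremReport:
    quotient: QuotientDomain
    iso: dict[int, Value]  # class index -> image element
    surjective: bool
    morphism_checked: int
    morphism_violations: list
    structure_checked: int
    structure_violations: list

    @property
    def ok(self) -> bool:
        return (
            self.surjective
            and not self.morphism_violations
            and not self.structure_violations
            and self.quotient.well_defined
        )


def first_isomorphism(
    source: FragmentBase,
    interp: Interpretation,
    target: FragmentBase,
    translation: TermTranslation | None = None,
    max_checks: int = 200_000,
) -> IsoTheoremReport:
    """Kernel quotient of a surjective structure-preserving map ~ its image.

    ``translation`` relates source schema terms to target schema terms
    (identity when omitted).  The class -> image bijection exists because
    classes are exactly the fibers; the report certifies that it preserves
    every induced operation within bounds.
    """
    F = translation or identity_translation(list(source.pi))
    # 1. interp must be a morphism: i(f_t(a..)) == f_F(t)(i(a)..), Kleene.
    violations = []
    checked = 0
    for t in source.pi:
        n = len(var_order(t))
        for combo in product(source.elements, repeat=n):
            if checked >= max_checks:
                break
            checked += 1
            left_src = source.apply(t, combo)
            if left_src is None:
                continue  # outside bounded fragment: no constraint
            right = target.apply(F.apply(t), [interp.map[a] for a in combo])
            left = interp.map[left_src]
            if right is not None and left != right:
                violations.append((t, combo, left, right))
    # 2. surjectivity onto the bounded target fragment.
    images = set(interp.map[e] for e in source.elements)
    surjective = all(b in images for b in target.elements)
    # 3. quotient by the kernel; bijection class -> image.
    partition = kernel_partition(interp)
    quotient = build_quotient(source, partition, max_checks=max_checks)
    iso = {i: interp.map[cls[0]] for i, cls in enumerate(partition.classes)}
    # 4. the bijection preserves the induced operations.
    structure_violations = []
    s_checked = 0
    for (t, class_idx), res in quotient.ops.items():
        out = target.apply(F.apply(t), [iso[i] for i in class_idx])
        s_checked += 1
        if out is not None and out != iso[res]:
            structure_violations.append((t, class_idx, iso[res], out))
    return IsoTheoremReport(
        quotient, iso, surjective, checked, violations, s_checked, structure_violations
    )
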