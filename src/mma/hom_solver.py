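"""Constructing and verifying F-homomorphisms between bounded domains.

An F-homomorphism h from (A, Pi) to (B, Psi) satisfies, for every t in Pi and
every tuple of source elements,

    h(f_t(a1..an)) = f_{F(t)}(h(a1)..h(an))

with F a variable-preserving term translation Pi -> Psi.  Given images for
the generators, h -- if it exists -- is forced: every element of the bounded
closure is the yield of some recorded application, and the equation above
propagates images layer by layer.  When two derivations of the same element
force different images the extension does not exist; the solver returns a
conflict witness (the element, its two derivations and the two images)
instead of a map.  Equality of partial results is Kleene equality: both
undefined counts as equal.

Certification is always relative to the closure bounds; reports carry the
``truncated`` flags of both domains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .contexts import UNDEFINED, Value
from .domain_closure import Application, Derivation, Domain, apply_operation
from .term_core import TermTranslation, render, term_key


class HomomorphismError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorMap:
    """The partial map h' on the source generators (the "analogical map")."""

    pairs: tuple[tuple[Value, Value], ...]

    def as_dict(self) -> dict[Value, Value]:
        return dict(self.pairs)


def generator_map(pairs: Mapping[Value, Value]) -> GeneratorMap:
    return GeneratorMap(tuple(sorted(pairs.items())))


@dataclass(frozen=True)
class ConflictWitness:
    element: Value
    derivation_a: Derivation
    derivation_b: Derivation
    image_a: Value
    image_b: Value

    def render(self) -> str:
        return (
            f"{self.element.render()}: {self.derivation_a.render()} -> "
            f"{self.image_a.render()}  vs  {self.derivation_b.render()} -> "
            f"{self.image_b.render()}"
        )


@dataclass
class Homomorphism:
    source: Domain
    target: Domain
    F: TermTranslation
    mapping: dict[Value, Value]
    status: str  # "certified" | "conflict"
    witness: ConflictWitness | None = None
    truncated: bool = False

    def __call__(self, v: Value) -> Value:
        if v is UNDEFINED or v.tag == "undefined":
            return UNDEFINED
        return self.mapping[v]


def _transfer(h_target: Domain, F: TermTranslation, app: Application, images) -> Value:
    """Image of one application under structure-preserving transfer."""
    if any(i is UNDEFINED or i.tag == "undefined" for i in images):
        return UNDEFINED
    return apply_operation(h_target.context, F.apply(app.term), images)


def extend_homomorphism(
    src: Domain, tgt: Domain, F: TermTranslation, g: GeneratorMap
) -> Homomorphism:
    """Propagate generator images along every recorded source application.

    Applications are processed in closure order (layer, then schema term,
    then canonical argument order), so a conflict -- when present -- is
    reported at the minimal-depth element, earliest in canonical order.
    """
    src_pi = set(src.spec.pi)
    if set(F.domain) != src_pi:
        raise HomomorphismError(
            "translation domain does not match the source schema Pi"
        )
    tgt_pi = set(tgt.spec.pi)
    for img in F.image:
        if img not in tgt_pi:
            raise HomomorphismError(
                f"translation image {render(img)} is not in the target schema"
            )
    mapping = g.as_dict()
    gens = set(src.spec.generators)
    if not gens <= set(mapping):
        missing = sorted(gens - set(mapping))[0]
        raise HomomorphismError(f"generator {missing.render()} has no image")
    for gen, img in mapping.items():
        if img.tag != tgt.context.carrier_tag:
            raise HomomorphismError(
                f"image {img.render()} of generator {gen.render()} is outside "
                f"the target carrier ({tgt.context.carrier_tag})"
            )
    first_deriv: dict[Value, Derivation] = {
        v: src.derivations[v][0] for v in mapping if v in src.derivations
    }
    for app in src.applications:
        images = [mapping[a] for a in app.args]
        img = _transfer(tgt, F, app, images)
        deriv = Derivation(
            "step", app.result, app.term, tuple(src.derivations[a][0] for a in app.args)
        )
        prev = mapping.get(app.result)
        if app.result not in mapping:
            mapping[app.result] = img
            first_deriv[app.result] = deriv
        elif prev != img:
            witness = ConflictWitness(
                app.result,
                first_deriv.get(app.result, src.derivations[app.result][0]),
                deriv,
                prev,
                img,
            )
            return Homomorphism(
                src, tgt, F, mapping, "conflict", witness,
                truncated=src.truncated or tgt.truncated,
            )
    return Homomorphism(
        src, tgt, F, mapping, "certified", None,
        truncated=src.truncated or tgt.truncated,
    )


def extend_homomorphism_dfs(
    src: Domain, tgt: Domain, F: TermTranslation, g: GeneratorMap
) -> dict[Value, Value]:
    """Alternative propagation order: canonical-order depth-first recursion.

    Follows, for each element, its first recorded derivation.  Used to check
    that the extension is independent of propagation order.
    """
    base = g.as_dict()
    cache: dict[Value, Value] = {}

    def image(v: Value) -> Value:
        if v in cache:
            return cache[v]
        if v in base and src.elements.get(v) == 0:
            cache[v] = base[v]
            return base[v]
        d = src.derivations[v][0]
        if d.kind == "gen":
            cache[v] = base[v]
            return base[v]
        imgs = [image(c.yields) for c in d.children]
        if any(i is UNDEFINED or i.tag == "undefined" for i in imgs):
            out = UNDEFINED
        else:
            out = apply_operation(tgt.context, F.apply(d.term), imgs)
        cache[v] = out
        return out

    for v in sorted(src.elements):
        image(v)
    return cache


@dataclass
class VerificationReport:
    checked: int
    violations: list[tuple[Application, Value, Value]]
    truncated: bool

    @property
    def ok(self) -> bool:
        return not self.violations


def verify_homomorphism(h: Homomorphism) -> VerificationReport:
    """Re-check the homomorphism equation on every recorded application."""
    if h.status != "certified":
        raise HomomorphismError("cannot verify a conflicted homomorphism")
    violations = []
    for app in h.source.applications:
        left = h.mapping[app.result]
        right = _transfer(h.target, h.F, app, [h.mapping[a] for a in app.args])
        if left != right:
            violations.append((app, left, right))
    return VerificationReport(len(h.source.applications), violations, h.truncated)


@dataclass
class IsoReport:
    status: str  # "iso" | "not_injective" | "not_surjective"
    inverse: dict[Value, Value] | None = None
    witness: tuple[Value, ...] | None = None
    inverse_certified: bool | None = None


def check_isomorphism(h: Homomorphism) -> IsoReport:
    """Decide bijectivity on the bounded element sets.

    When bijective and F is itself invertible termwise, the inverse map is
    additionally certified to be an F^-1-homomorphism against the target's
    recorded applications.
    """
    if h.status != "certified":
        raise HomomorphismError("cannot check isomorphism of a conflicted map")
    inverse: dict[Value, Value] = {}
    for v in sorted(h.source.elements):
        img = h.mapping[v]
        if img in inverse:
            return IsoReport("not_injective", witness=(inverse[img], v))
        inverse[img] = v
    uncovered = [b for b in sorted(h.target.elements) if b not in inverse]
    if uncovered:
        return IsoReport("not_surjective", witness=(uncovered[0],))
    certified: bool | None = None
    try:
        Finv = h.F.inverse()
    except Exception:
        Finv = None
    if Finv is not None:
        certified = True
        for app in h.target.applications:
            left = inverse.get(app.result, UNDEFINED)
            imgs = [inverse[a] for a in app.args]
            right = apply_operation(h.source.context, Finv.apply(app.term), imgs)
            if left != right:
                certified = False
                break
    return IsoReport("iso", inverse=inverse, inverse_certified=certified)
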