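"""Proportional analogy problems a : b :: c : ?  -- file format and solver.

A problem file (YAML) declares a source domain, a target domain, a term
translation, a generator map and the three query items.  The same surface
problem may admit several *modelings* -- different schemas and translations
that yield different answers -- so a file carries a list of them and the
solver reports one answer record per modeling.

Solving is deterministic: generate both bounded closures, check the items
are where they should be, propagate the generator map; a certified extension
answers h(b) (with a consistency flag recording whether h(a) == c), a
conflict returns the witness instead.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Mapping

import yaml

from .contexts import Context, Value, builtin_context, parse_value
from .domain_closure import Bounds, Domain, DomainSpec, generate_closure
from .hom_solver import (
    ConflictWitness,
    GeneratorMap,
    Homomorphism,
    extend_homomorphism,
    generator_map,
)
from .term_core import Term, TermTranslation, make_translation, parse_term, render


class ProblemSpecError(ValueError):
    pass


_CONTEXT_BUILDERS = {"strings", "strings_succ", "rationals", "integers"}


def _build_context(node: Any, path: str) -> Context:
    if isinstance(node, str):
        name = node
        params: dict = {}
    elif isinstance(node, Mapping):
        name = node.get("name")
        params = {k: v for k, v in node.items() if k != "name"}
    else:
        raise ProblemSpecError(f"{path}: context must be a name or a mapping")
    try:
        return builtin_context(name, **params)
    except Exception as exc:
        raise ProblemSpecError(f"{path}: {exc}") from exc


@dataclass
class Modeling:
    name: str
    source: DomainSpec
    target: DomainSpec
    translation: TermTranslation
    gmap: GeneratorMap


@dataclass
class ProblemSpec:
    name: str
    modelings: list[Modeling]
    item_a: str
    item_b: str
    item_c: str
    bounds: Bounds
    variables: tuple[str, ...] = ("x1", "x2", "x3")

    def items_for(self, m: Modeling) -> tuple[Value, Value, Value]:
        a = parse_value(self.item_a, m.source.context)
        b = parse_value(self.item_b, m.source.context)
        c = parse_value(self.item_c, m.target.context)
        return a, b, c


def _require(node: Mapping, key: str, path: str) -> Any:
    if key not in node:
        raise ProblemSpecError(f"{path}: missing required field {key!r}")
    return node[key]


def _parse_modeling(node: Mapping, name: str, variables: list[str]) -> Modeling:
    src_node = _require(node, "source", name)
    tgt_node = _require(node, "target", name)

    def side(sn: Mapping, label: str, schema_key: str) -> DomainSpec:
        ctx = _build_context(_require(sn, "context", f"{name}.{label}"), f"{name}.{label}")
        terms = [
            parse_term(s, ctx.signature, variables)
            for s in _require(sn, schema_key, f"{name}.{label}")
        ]
        gens = tuple(
            parse_value(str(g), ctx)
            for g in _require(sn, "generators", f"{name}.{label}")
        )
        return DomainSpec(ctx, tuple(terms), gens, label)

    source = side(src_node, "source", "pi")
    target = side(tgt_node, "target", "psi")
    trans_node = _require(node, "translation", name)
    pairs = []
    for s_text, i_text in trans_node.items():
        s = parse_term(s_text, source.context.signature, variables)
        i = parse_term(i_text, target.context.signature, variables)
        pairs.append((s, i))
    try:
        translation = make_translation(pairs)
    except Exception as exc:
        raise ProblemSpecError(f"{name}.translation: {exc}") from exc
    gmap_node = _require(node, "generator_map", name)
    gmap = generator_map(
        {
            parse_value(str(k), source.context): parse_value(str(v), target.context)
            for k, v in gmap_node.items()
        }
    )
    return Modeling(name, source, target, translation, gmap)


def parse_problem(doc: Mapping) -> ProblemSpec:
    name = doc.get("name", "problem")
    variables = [str(v) for v in doc.get("variables", ["x1", "x2", "x3"])]
    items = _require(doc, "items", name)
    for k in ("a", "b", "c"):
        _require(items, k, f"{name}.items")
    bounds_node = doc.get("bounds", {})
    bounds = Bounds(
        depth=bounds_node.get("depth", 4),
        max_len=bounds_node.get("max_len", 64),
        max_size=bounds_node.get("max_size", 20_000),
        max_apps=bounds_node.get("max_apps", 200_000),
    )
    if "modelings" in doc:
        modelings = [
            _parse_modeling(m, m.get("name", f"{name}[{i}]"), variables)
            for i, m in enumerate(doc["modelings"])
        ]
    else:
        modelings = [_parse_modeling(doc, name, variables)]
    return ProblemSpec(
        name, modelings, str(items["a"]), str(items["b"]), str(items["c"]),
        bounds, tuple(variables),
    )


def load_problem(path) -> ProblemSpec:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise ProblemSpecError(f"{path}: not a mapping document")
    return parse_problem(doc)


def load_bundled(name: str) -> ProblemSpec:
    """Load one of the packaged example problems (example_0_3 ... example_0_7)."""
    text = resources.files("mma.data").joinpath(f"{name}.yaml").read_text()
    return parse_problem(yaml.safe_load(io.StringIO(text)))


BUNDLED_PROBLEMS = (
    "example_0_3",
    "example_0_4",
    "example_0_5",
    "example_0_6",
    "example_0_7",
)


def _context_doc(ctx: Context) -> str:
    return ctx.name


def to_document(p: ProblemSpec) -> dict:
    """Canonical document form; ``parse_problem`` round-trips it."""

    def modeling_doc(m: Modeling) -> dict:
        return {
            "name": m.name,
            "source": {
                "context": _context_doc(m.source.context),
                "pi": [render(t) for t in m.source.pi],
                "generators": [g.render() for g in m.source.generators],
            },
            "target": {
                "context": _context_doc(m.target.context),
                "psi": [render(t) for t in m.target.pi],
                "generators": [g.render() for g in m.target.generators],
            },
            "translation": {render(s): render(i) for s, i in m.translation.pairs},
            "generator_map": {k.render(): v.render() for k, v in m.gmap.pairs},
        }

    doc: dict = {
        "name": p.name,
        "variables": list(p.variables),
        "items": {"a": p.item_a, "b": p.item_b, "c": p.item_c},
        "bounds": {
            "depth": p.bounds.depth,
            "max_len": p.bounds.max_len,
            "max_size": p.bounds.max_size,
            "max_apps": p.bounds.max_apps,
        },
    }
    if len(p.modelings) == 1:
        doc.update(modeling_doc(p.modelings[0]))
    else:
        doc["modelings"] = [modeling_doc(m) for m in p.modelings]
    return doc


def dump_problem(p: ProblemSpec) -> str:
    return yaml.safe_dump(to_document(p), sort_keys=False)


@dataclass
class AnswerRecord:
    modeling: str
    status: str  # "answer" | "no_solution" | "item_missing"
    value: Value | None = None
    witness: ConflictWitness | None = None
    missing: str | None = None
    consistency: bool | None = None  # h(a) == c
    truncated: bool = False
    homomorphism: Homomorphism | None = None

    def to_json(self) -> dict:
        out: dict[str, Any] = {"modeling": self.modeling, "status": self.status}
        if self.status == "answer":
            out["answer"] = self.value.render()
            out["consistency"] = self.consistency
        elif self.status == "no_solution":
            out["conflict_element"] = self.witness.element.render()
            out["images"] = [
                self.witness.image_a.render(),
                self.witness.image_b.render(),
            ]
        else:
            out["missing"] = self.missing
        out["truncated"] = self.truncated
        return out


def solve_modeling(p: ProblemSpec, m: Modeling) -> AnswerRecord:
    a, b, c = p.items_for(m)
    src = generate_closure(m.source, p.bounds)
    tgt = generate_closure(m.target, p.bounds)
    truncated = src.truncated or tgt.truncated
    for item, dom, label in ((a, src, "a"), (b, src, "b"), (c, tgt, "c")):
        if item not in dom:
            return AnswerRecord(
                m.name, "item_missing", missing=label, truncated=truncated
            )
    h = extend_homomorphism(src, tgt, m.translation, m.gmap)
    if h.status == "conflict":
        return AnswerRecord(
            m.name, "no_solution", witness=h.witness, truncated=h.truncated
        )
    return AnswerRecord(
        m.name,
        "answer",
        value=h.mapping[b],
        consistency=h.mapping[a] == c,
        truncated=h.truncated,
        homomorphism=h,
    )


def solve_proportional(p: ProblemSpec) -> list[AnswerRecord]:
    """One answer record per modeling, in file order."""
    return [solve_modeling(p, m) for m in p.modelings]
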