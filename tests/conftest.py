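import pytest

from mma.case_studies import (
    fraction_diagram_setup,
    fraction_model,
    numbered_game_model,
)
from mma.contexts import builtin_context, string_value
from mma.domain_closure import Bounds, DomainSpec, generate_closure
from mma.rerepresentation import apply_theorem, riddle_fixture
from mma.term_core import parse_term


@pytest.fixture(scope="session")
def strings_ctx():
    return builtin_context("strings")


@pytest.fixture(scope="session")
def strings_succ_ctx():
    return builtin_context("strings_succ")


@pytest.fixture(scope="session")
def append_reverse_schema(strings_ctx):
    """The two operations of the running string example: append, and
    append-after-reversing-the-second."""
    p = lambda s: parse_term(s, strings_ctx.signature, ["x1", "x2"])
    return (p("lambda(x1, x2)"), p("lambda(x1, sigma(x2))"))


@pytest.fixture(scope="session")
def two_string_domain(strings_ctx, append_reverse_schema):
    """Closure of {ab, p} under append / append-reversed (depth 2)."""
    spec = DomainSpec(
        strings_ctx,
        append_reverse_schema,
        (string_value("ab"), string_value("p")),
    )
    return generate_closure(spec, Bounds(depth=2))


@pytest.fixture(scope="session")
def riddle():
    return riddle_fixture()


@pytest.fixture(scope="session")
def riddle_theorem(riddle):
    setup, _ = riddle
    return apply_theorem(setup)


@pytest.fixture(scope="session")
def fractions():
    return fraction_model()


@pytest.fixture(scope="session")
def fraction_diagram():
    return fraction_diagram_setup()


@pytest.fixture(scope="session")
def fraction_theorem(fraction_diagram):
    return apply_theorem(fraction_diagram)


@pytest.fixture(scope="session")
def board():
    return numbered_game_model()
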