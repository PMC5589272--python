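import random

import pytest

from mma.term_core import (
    App,
    Signature,
    Symbol,
    TermError,
    TranslationError,
    UndecomposableTermError,
    Var,
    extend_term_morphism,
    free_fragment,
    identity_translation,
    make_translation,
    match,
    parse_term,
    render,
    substitute,
    term_depth,
    variables_of,
)

VARS = ["x1", "x2", "x3"]


@pytest.fixture(scope="module")
def sig():
    return Signature(
        [Symbol("lambda", 2), Symbol("sigma", 1), Symbol("suc", 1), Symbol("pre", 1)]
    )


class TestParseRender:
    @pytest.mark.parametrize(
        "text",
        [
            "lambda(x1, sigma(x2))",
            "x1",
            "lambda(lambda(x1, x2), lambda(x2, x1))",
            "suc(pre(x3))",
        ],
    )
    def test_roundtrip_on_canonical_text(self, sig, text):
        assert render(parse_term(text, sig, VARS)) == text

    def test_structure(self, sig):
        t = parse_term("lambda(x1, sigma(x2))", sig, VARS)
        assert isinstance(t, App) and t.symbol.name == "lambda"
        assert t.args[0] == Var("x1")
        assert t.args[1] == App(sig["sigma"], (Var("x2"),))

    def test_greek_aliases_accepted_ascii_canonical(self, sig):
        t = parse_term("λ(x1, γ⁻¹(σ(x2)))", sig, VARS)
        assert render(t) == "lambda(x1, pre(sigma(x2)))"

    @pytest.mark.parametrize(
        "bad",
        ["lambda(x1)", "unknown(x1)", "lambda(x1, x2", "lambda(x1,, x2)", ""],
    )
    def test_errors_are_parse_errors(self, sig, bad):
        with pytest.raises(TermError):
            parse_term(bad, sig, VARS)

    def test_whitespace_insignificant(self, sig):
        a = parse_term("lambda( x1 ,sigma(  x2) )", sig, VARS)
        b = parse_term("lambda(x1, sigma(x2))", sig, VARS)
        assert a == b


class TestSubstitute:
    def test_constant_bindings(self, sig):
        t = parse_term("lambda(x1, x2)", sig, VARS)
        ab, p = Var("ab"), Var("p")
        assert render(substitute(t, {"x1": ab, "x2": p})) == "lambda(ab, p)"

    def test_identity_bindings_leave_term_unchanged(self, sig):
        t = parse_term("lambda(x1, sigma(x2))", sig, VARS)
        assert substitute(t, {v: Var(v) for v in VARS[:2]}) == t

    def test_nested_replacement(self, sig):
        # independent re-application of the replacement rule by hand:
        # s = lambda(x1, sigma(x2)), x2 -> lambda(x1, x1)
        s = parse_term("lambda(x1, sigma(x2))", sig, VARS)
        inner = parse_term("lambda(x1, x1)", sig, VARS)
        out = substitute(s, {"x1": Var("x1"), "x2": inner})
        assert render(out) == "lambda(x1, sigma(lambda(x1, x1)))"

    def test_missing_binding_raises(self, sig):
        t = parse_term("lambda(x1, x2)", sig, VARS)
        with pytest.raises(TermError, match="x2"):
            substitute(t, {"x1": Var("x1")})

    def test_composition_law_with_ground_outer(self, sig):
        # substitute(substitute(t, b1), b2) == substitute(t, b2 . b1)
        rng = random.Random(11)
        ground = [Var("a"), Var("b"), parse_term("sigma(x3)", sig, VARS)]

        def random_term(depth):
            if depth == 0 or rng.random() < 0.3:
                return Var(rng.choice(VARS))
            sym = sig[rng.choice(["lambda", "sigma"])]
            return App(sym, tuple(random_term(depth - 1) for _ in range(sym.arity)))

        b2 = {"x1": ground[0], "x2": ground[1], "x3": ground[2]}
        for _ in range(50):
            t = random_term(3)
            b1 = {v: random_term(2) for v in VARS}
            lhs = substitute(substitute(t, b1), b2)
            composed = {v: substitute(b1[v], b2) for v in VARS}
            assert lhs == substitute(t, composed)


class TestVariablesOf:
    def test_read_off(self, sig):
        assert variables_of(parse_term("lambda(x1, sigma(x2))", sig, VARS)) == {
            "x1",
            "x2",
        }
        assert variables_of(Var("x3")) == {"x3"}

    def test_swapped_term_has_equal_variable_set(self, sig):
        a = parse_term("lambda(x1, x2)", sig, VARS)
        b = parse_term("lambda(x2, x1)", sig, VARS)
        assert variables_of(a) == variables_of(b)


class TestTranslation:
    def test_variable_preserving_pairs_accepted(self, sig):
        F = make_translation(
            [
                (parse_term("lambda(x1, x2)", sig, VARS), parse_term("lambda(x2, x1)", sig, VARS)),
                (parse_term("suc(x3)", sig, VARS), parse_term("pre(x3)", sig, VARS)),
            ]
        )
        assert len(F.pairs) == 2

    def test_variable_loss_rejected_naming_pair(self, sig):
        with pytest.raises(TranslationError, match="lambda"):
            make_translation(
                [(parse_term("lambda(x1, x2)", sig, VARS), parse_term("suc(x1)", sig, VARS))]
            )

    def test_identity_translation(self, sig):
        pi = [parse_term("lambda(x1, x2)", sig, VARS)]
        F = identity_translation(pi)
        assert F.apply(pi[0]) == pi[0]


class TestTermMorphism:
    @pytest.fixture()
    def copycat_F(self, sig):
        # append -> swapped append, successor -> predecessor
        return make_translation(
            [
                (parse_term("lambda(x1, x2)", sig, VARS), parse_term("lambda(x2, x1)", sig, VARS)),
                (parse_term("suc(x3)", sig, VARS), parse_term("pre(x3)", sig, VARS)),
            ]
        )

    def test_recursion_on_nested_term(self, sig, copycat_F):
        t = parse_term("lambda(x1, suc(x2))", sig, VARS)
        table = extend_term_morphism(copycat_F, [t])
        assert table.status == "consistent"
        assert render(table.apply(t)) == "lambda(pre(x2), x1)"

    def test_variables_fixed_and_agrees_with_base(self, sig, copycat_F):
        pi = list(copycat_F.domain)
        table = extend_term_morphism(copycat_F, pi + [Var("x1")])
        assert table.apply(Var("x1")) == Var("x1")
        for t in pi:
            assert table.apply(t) == copycat_F.apply(t)

    def test_all_decompositions_must_agree(self, sig):
        # overlapping patterns sent to incompatible images: a term matching
        # both decompositions is a witness of inconsistency
        t_plain = parse_term("lambda(x1, x2)", sig, VARS)
        t_spec = parse_term("lambda(sigma(x1), x2)", sig, VARS)
        t_sig = parse_term("sigma(x3)", sig, VARS)
        F = make_translation(
            [
                (t_plain, parse_term("lambda(x2, x1)", sig, VARS)),
                (t_spec, t_spec),
                (t_sig, t_sig),
            ]
        )
        probe = parse_term("lambda(sigma(x1), x2)", sig, VARS)
        table = extend_term_morphism(F, [probe])
        assert table.status == "inconsistent"
        assert table.witness == probe

    def test_nonoverlapping_fixture_schemas_are_consistent(self, sig, copycat_F):
        fragment = free_fragment(list(copycat_F.domain), VARS, depth=3)
        assert extend_term_morphism(copycat_F, fragment).status == "consistent"

    def test_undecomposable_term(self, sig, copycat_F):
        with pytest.raises(UndecomposableTermError):
            extend_term_morphism(copycat_F, [parse_term("sigma(x1)", sig, VARS)])

    def test_nonlinear_pattern_requires_equal_subterms(self, sig):
        pat = parse_term("lambda(x1, x1)", sig, VARS)
        assert match(pat, parse_term("lambda(sigma(x2), sigma(x2))", sig, VARS))
        assert match(pat, parse_term("lambda(x1, x2)", sig, VARS)) is None


def test_free_fragment_layers(sig):
    pi = [parse_term("lambda(x1, x2)", sig, VARS)]
    frag = free_fragment(pi, ["x1", "x2"], depth=2)
    assert Var("x1") in frag
    assert parse_term("lambda(x1, x2)", sig, VARS) in frag
    assert parse_term("lambda(lambda(x1, x2), x1)", sig, VARS) in frag
    assert all(term_depth(t) <= 3 for t in frag)
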