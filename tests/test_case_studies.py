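from fractions import Fraction

import pytest

from mma.case_studies import (
    circular_board_report,
    commutation_census,
    enumerate_fraction_fragment,
    eq19_check,
    error_rule_analysis,
    fraction_conceptual_eval,
    fraction_model,
    fraction_procedural_normalize,
    rote_learner_ablation,
    table4_membership,
)
from mma.contexts import box_value, integer_value, rational_value
from mma.hom_solver import check_isomorphism
from mma.term_core import render


class TestNumberedGame:
    def test_box_to_number_map_is_an_isomorphism(self, board):
        assert board.h.status == "certified"
        report = check_isomorphism(board.h)
        assert report.status == "iso" and report.inverse_certified

    def test_interpretation_binds_tokens_to_boxes_and_numbers(self, board):
        from mma.domain_closure import evaluate_interpretation

        t = next(t for t in board.spatial.spec.pi if t.symbol.name == "go_to_right")
        assert evaluate_interpretation(
            board.spatial.context, t, {"X": box_value(3)}
        ) == box_value(4)
        assert board.h.mapping[box_value(3)] == integer_value(3)

    def test_boundary_is_kleene_equal(self, board):
        from mma.contexts import UNDEFINED, eval_symbol

        assert eval_symbol(board.spatial.context, "go_to_right", [box_value(10)]) is UNDEFINED
        assert eval_symbol(board.numeric.context, "successor", [integer_value(10)]) is UNDEFINED

    def test_census_commutes_for_all_hundred_assignments(self, board):
        commuting, total, failures = commutation_census(board)
        assert total == board.n ** 2 == 100
        assert commuting == total and not failures

    def test_sabotaged_map_fails_the_census(self, board):
        mapping = dict(board.h.mapping)
        mapping[box_value(2)], mapping[box_value(3)] = (
            mapping[box_value(3)],
            mapping[box_value(2)],
        )
        commuting, total, failures = commutation_census(board, mapping)
        assert commuting < total
        assignment, term, left, right = failures[0]
        assert left != right  # a named failing (assignment, term) pair


class TestCircularBoard:
    def test_chord_to_tenth_box_shorter_than_to_sixth(self):
        rep = circular_board_report(10)
        assert rep.chord[(1, 10)] < rep.chord[(1, 6)]
        assert rep.distance_violations

    def test_left_of_paradox(self):
        rep = circular_board_report(10)
        assert rep.left_of[(1, 2)]
        assert rep.left_of[(10, 1)] and rep.left_of[(10, 2)]
        assert rep.order_cycle and rep.order_cycle[0] == rep.order_cycle[-1]

    def test_linear_control_has_no_violations(self):
        rep = circular_board_report(10, shape="linear")
        assert rep.distance_violations == []
        assert rep.order_cycle == []

    def test_small_boards_rejected(self):
        with pytest.raises(ValueError):
            circular_board_report(2)


class TestFractionRoutes:
    def test_nested_division_lands_in_five_sixteenths(self, fractions):
        t = fractions.parse("div(1/4, plus(3/15, 3/5))")
        assert fraction_procedural_normalize(fractions, t) == rational_value(
            Fraction(5, 16)
        )

    def test_two_halves_conceptually_one_pizza(self, fractions):
        t = fractions.parse("plus(1/2, 1/2)")
        assert fraction_conceptual_eval(fractions, t) == rational_value(1)
        assert fraction_procedural_normalize(fractions, t) == rational_value(1)

    def test_literal_is_its_own_representative(self, fractions):
        t = fractions.parse("3/4")
        assert fraction_procedural_normalize(fractions, t) == rational_value(
            Fraction(3, 4)
        )
        assert fraction_conceptual_eval(fractions, t) == rational_value(Fraction(3, 4))

    def test_division_by_zero_propagates(self, fractions):
        t = fractions.parse("div(1/2, plus(0/1, 0/2))")
        assert fraction_procedural_normalize(fractions, t).tag == "undefined"

    def test_routes_agree_on_the_enumerated_fragment(self, fractions):
        fragment = enumerate_fraction_fragment(fractions)
        checked, disagreements = eq19_check(fractions, fragment)
        assert checked == len(fragment) > 5000
        assert disagreements == []


class TestTable4:
    def test_documented_memberships(self, fractions):
        groups = table4_membership(
            fractions,
            [
                "1/4", "3/12", "plus(3/24, 1/8)", "div(1/2, 2/1)",
                "1/2", "6/12", "div(1/4, 1/2)",
                "12/12", "div(5/5, 3/3)",
            ],
        )
        assert set(groups["1/4"]) == {"1/4", "3/12", "plus(3/24, 1/8)", "div(1/2, 2/1)"}
        assert set(groups["1/2"]) == {"1/2", "6/12", "div(1/4, 1/2)"}
        assert set(groups["1"]) == {"12/12", "div(5/5, 3/3)"}

    def test_two_terms_share_a_class_iff_values_equal(self, fractions):
        # cross-check against an independent evaluator: a tiny standalone
        # parser over the rendered text using Fraction arithmetic only
        import fractions as pyfractions

        def ev(t):
            if "(" not in t:
                a, b = t.split("/")
                return pyfractions.Fraction(int(a), int(b))
            head, inner = t.split("(", 1)
            inner = inner.rsplit(")", 1)[0]
            depth = 0
            for i, c in enumerate(inner):
                if c == "(":
                    depth += 1
                elif c == ")":
                    depth -= 1
                elif c == "," and depth == 0:
                    left, right = inner[:i], inner[i + 2 :]
                    break
            a, b = ev(left), ev(right)
            return a + b if head == "plus" else a / b

        samples = ["plus(1/2, 1/4)", "3/4", "div(3/4, 1/1)", "plus(1/3, 1/6)", "1/2"]
        keyed = {}
        for s in samples:
            v = fraction_procedural_normalize(fractions, fractions.parse(s))
            keyed.setdefault(v, []).append(s)
        for v, members in keyed.items():
            vals = {ev(m.replace(" ", "").replace(",", ", ")) for m in members}
            assert len(vals) == 1 and vals == {
                pyfractions.Fraction(*v.key)
            }


class TestErrorRules:
    def test_mediant_conflates_one_with_one_half_on_the_restricted_fragment(
        self, fractions
    ):
        report = error_rule_analysis(fractions, "mediant", ["1/2", "plus(1/2, 1/2)"])
        assert report.respects_kernel
        assert ("1", "1/2") in report.merged_classes

    def test_mediant_breaks_the_kernel_on_a_wider_fragment(self, fractions):
        fragment = [
            f"plus({a}/{b}, {c}/{d})"
            for a in range(1, 7) for b in range(1, 7)
            for c in range(1, 7) for d in range(1, 7)
            if (a, b) <= (c, d)
        ]
        report = error_rule_analysis(fractions, "mediant", fragment)
        assert not report.respects_kernel
        w1, w2 = report.witness
        # the witness really is a pi_beta-equivalent pair with distinct e-values
        assert fraction_procedural_normalize(
            fractions, w1
        ) == fraction_procedural_normalize(fractions, w2)

    def test_exact_rule_factors_injectively(self, fractions):
        report = error_rule_analysis(
            fractions, "exact", ["1/2", "plus(1/2, 1/2)", "1/1", "plus(1/4, 1/4)"]
        )
        assert report.respects_kernel and report.merged_classes == []


class TestRoteLearner:
    def test_class_structure_survives_the_ablation(self, fractions):
        fragment = ["1/2", "plus(1/2, 1/2)", "plus(1/3, 1/6)", "div(1/4, 1/2)"]
        report = rote_learner_ablation(fractions, fragment)
        assert report.classes_identical

    def test_proximity_needs_the_conceptual_route(self, fractions):
        report = rote_learner_ablation(
            fractions, ["1/2"], queries=["plus(2/3, 1/4)"]
        )
        assert report.proximity_conceptual["plus(2/3, 1/4)"] == "1/12"
        assert "unavailable" in report.proximity_ablated
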