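import pytest

from mma.contexts import box_value, person_value, string_value
from mma.hom_solver import extend_homomorphism, generator_map
from mma.quotient_coeq import Interpretation, Partition, kernel_partition
from mma.rerepresentation import (
    DiagramSetup,
    check_lemma,
    mgu_contrast,
    mgu_properties,
    riddle_fixture,
    riddle_person_partition,
)
from mma.term_core import Var, identity_translation, render


def _class_renders(partition):
    return [{render(t) for t in cls} for cls in partition.classes]


class TestLemma:
    def test_riddle_diagram_commutes_on_the_full_fragment(self, riddle):
        setup, _ = riddle
        report = check_lemma(setup)
        assert report.commutes and report.checked > 100

    def test_identity_setup_commutes_trivially(self, two_string_domain):
        F = identity_translation(list(two_string_domain.spec.pi))
        g = generator_map({v: v for v in two_string_domain.spec.generators})
        h = extend_homomorphism(two_string_domain, two_string_domain, F, g)
        setup = DiagramSetup(
            F, h, {"v1": string_value("ab"), "v2": string_value("p")}, depth=2
        )
        report = check_lemma(setup)
        assert report.commutes

    def test_board_game_assignment_sends_distance_to_two(self, board):
        setup = DiagramSetup(
            board.F, board.h, {"X": box_value(3), "Y": box_value(5)}, depth=2
        )
        report = check_lemma(setup)
        assert report.commutes
        # both routes send the stroll-distance symbol to the number two
        from mma.domain_closure import evaluate_interpretation

        t = next(t for t in setup.pi if t.symbol.name == "stroll_distance")
        alpha_t = evaluate_interpretation(
            board.spatial.context, t, setup.alpha0
        )
        assert board.h.mapping[alpha_t].payload == 2

    def test_fraction_diagram_commutes(self, fraction_diagram):
        report = check_lemma(fraction_diagram)
        assert report.commutes and report.checked > 1000


class TestTheorem:
    def test_riddle_quotients_have_three_person_classes(self, riddle_theorem):
        assert len(riddle_theorem.quotient_src.partition) == 3
        assert len(riddle_theorem.quotient_tgt.partition) == 3

    def test_triangles_and_square_commute(self, riddle_theorem):
        assert riddle_theorem.triangle_src.commutes
        assert riddle_theorem.triangle_tgt.commutes
        assert riddle_theorem.square.commutes

    def test_h_star_maps_son_class_to_daughter_class(self, riddle, riddle_theorem):
        setup, _ = riddle
        rep = riddle_theorem
        son_s1 = next(
            t
            for cls in rep.quotient_src.partition.classes
            for t in cls
            if render(t) == "son(S1)"
        )
        src_idx = rep.quotient_src.partition.class_of(son_s1)
        tgt_cls = rep.quotient_tgt.partition.classes[rep.h_star[src_idx]]
        assert "daughter(daughter(F1))" in {render(t) for t in tgt_cls}

    def test_h_star_agrees_with_transport_through_f_star(self, riddle, riddle_theorem):
        # computing h* as b^-1 . h . a must agree with pushing each source
        # class through F* and reading the target class
        from mma.term_core import extend_term_morphism

        setup, _ = riddle
        rep = riddle_theorem
        table = extend_term_morphism(
            setup.F, [t for cls in rep.quotient_src.partition.classes for t in cls]
        )
        for i, cls in enumerate(rep.quotient_src.partition.classes):
            for t in cls:
                assert rep.quotient_tgt.partition.class_of(table.apply(t)) == rep.h_star[i]

    def test_degenerate_identity_theorem(self, two_string_domain):
        from mma.rerepresentation import apply_theorem

        F = identity_translation(list(two_string_domain.spec.pi))
        g = generator_map({v: v for v in two_string_domain.spec.generators})
        h = extend_homomorphism(two_string_domain, two_string_domain, F, g)
        setup = DiagramSetup(
            F, h, {"v1": string_value("ab"), "v2": string_value("p")}, depth=2
        )
        rep = apply_theorem(setup)
        assert rep.commutes
        assert all(rep.h_star[i] == i for i in rep.h_star)

    def test_fraction_theorem_commutes(self, fraction_theorem):
        assert fraction_theorem.commutes
        # literal tokens 1/1 and 2/2 land in one class: re-representation
        ones = [
            cls
            for cls in fraction_theorem.quotient_src.partition.classes
            if Var("1/1") in cls
        ]
        assert ones and Var("2/2") in ones[0]


class TestRiddleTables:
    def test_source_table_memberships(self, riddle):
        setup, expected = riddle
        p = riddle_person_partition(setup, "source")
        renders = _class_renders(p)
        for person, members in expected["source_classes"].items():
            assert any(set(members) <= cls for cls in renders), person

    def test_target_table_memberships(self, riddle):
        setup, expected = riddle
        p = riddle_person_partition(setup, "target")
        renders = _class_renders(p)
        for person, members in expected["target_classes"].items():
            assert any(set(members) <= cls for cls in renders), person

    @pytest.mark.parametrize("side", ["source", "target"])
    def test_exactly_three_person_classes(self, riddle, side):
        setup, expected = riddle
        p = riddle_person_partition(setup, side)
        assert len(p) == expected["person_class_count"]


class TestMguContrast:
    def test_source_partition_merges_father_and_son_applications(self, riddle):
        setup, _ = riddle
        p = riddle_person_partition(setup, "source")
        pairs = {
            frozenset((render(a), render(b))) for _, a, b in mgu_contrast(p)
        }
        assert frozenset(("son(F1)", "father(S2)")) in pairs

    def test_target_partition_merges_daughter_and_mother_applications(self, riddle):
        setup, _ = riddle
        p = riddle_person_partition(setup, "target")
        pairs = {
            frozenset((render(a), render(b))) for _, a, b in mgu_contrast(p)
        }
        assert frozenset(("daughter(F1)", "mother(S2)")) in pairs

    def test_singleton_partition_has_no_witnesses(self, riddle):
        setup, _ = riddle
        p = riddle_person_partition(setup, "source")
        singletons = Partition([[t] for cls in p.classes for t in cls])
        assert mgu_contrast(singletons) == []

    def test_injective_interpretation_kernel_has_no_witnesses(self, riddle):
        setup, _ = riddle
        p = riddle_person_partition(setup, "source")
        terms = [t for cls in p.classes for t in cls]
        from mma.contexts import integer_value

        inj = Interpretation(
            "inj", terms, {t: integer_value(i) for i, t in enumerate(terms)}
        )
        assert mgu_contrast(kernel_partition(inj)) == []

    def test_remaining_properties_reported_informationally(self, riddle):
        setup, _ = riddle
        p = riddle_person_partition(setup, "source")
        report = mgu_properties(p)
        assert set(report) == {"proper_subterm", "argumentwise"}
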