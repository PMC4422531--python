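"""Axiom assembly, simplification and definition-precision scoring."""

import pytest
from hypothesis import given, settings, strategies as st

from eldef.definitions import (
    AssemblyError,
    CandidateDefinition,
    assemble_definition,
    defpre,
    read_back_triples,
    render_definition,
    simplify_definition,
)
from eldef.ontology import RelTriple, inferred_relationship_base


class TestAssemble:
    def test_baritosis_definition_from_two_triples(self):
        d = assemble_definition(
            "Baritosis",
            [
                RelTriple("Baritosis", "Isa", "Pneumoconiosis"),
                RelTriple("Baritosis", "Causative_agent", "Barium_dust"),
            ],
            isa_role="Isa",
        )
        assert d.named_parents == {"Pneumoconiosis"}
        assert d.existentials == {("Causative_agent", "Barium_dust")}

    def test_single_triple_base_case(self):
        d = assemble_definition("A", [RelTriple("A", "R", "B")])
        assert d.named_parents == frozenset()
        assert d.existentials == {("R", "B")}

    def test_multi_conjunct_shape(self):
        # five triples, repeated roles: one axiom with five existentials
        triples = [
            RelTriple("FoxFordyce", "Finding_site", "Apocrine_glands"),
            RelTriple("FoxFordyce", "Finding_site", "Apocrine_ducts"),
            RelTriple("FoxFordyce", "Causative_agent", "Obstruction"),
            RelTriple("FoxFordyce", "Causative_agent", "Rupture"),
            RelTriple("FoxFordyce", "Associated_morphology", "Papular_eruptions"),
        ]
        d = assemble_definition("FoxFordyce", triples)
        assert len(d.existentials) == 5 and not d.named_parents

    def test_empty_triples_rejected(self):
        with pytest.raises(AssemblyError):
            assemble_definition("A", [])

    def test_foreign_subject_rejected(self):
        with pytest.raises(AssemblyError):
            assemble_definition("A", [RelTriple("B", "R", "C")])


class TestReadBack:
    @given(
        st.sets(
            st.tuples(
                st.sampled_from(["Isa", "R1", "R2"]),
                st.sampled_from(["B1", "B2", "B3", "B4"]),
            ),
            min_size=1,
            max_size=6,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_roundtrip_equals_dedup(self, pairs):
        triples = [RelTriple("A", r, b) for r, b in pairs]
        d = assemble_definition("A", triples, isa_role="Isa")
        assert read_back_triples(d, isa_role="Isa") == frozenset(triples)

    def test_baritosis_definition_yields_two_triples(self):
        d = CandidateDefinition(
            "Baritosis",
            frozenset({"Pneumoconiosis"}),
            frozenset({("Causative_agent", "Barium_dust")}),
        )
        assert len(read_back_triples(d, isa_role="Isa")) == 2

    def test_parents_only_without_isa_role_warns_and_drops(self, caplog):
        d = CandidateDefinition("A", frozenset({"P"}), frozenset())
        with caplog.at_level("WARNING"):
            triples = read_back_triples(d, isa_role=None)
        assert triples == frozenset()
        assert "isa_role" in caplog.text


class TestSimplify:
    def test_general_parent_dropped(self, baritosis_tbox):
        d = CandidateDefinition(
            "Baritosis", frozenset({"Dust", "Barium_dust"}), frozenset()
        )
        assert simplify_definition(d, baritosis_tbox).named_parents == {"Barium_dust"}

    def test_general_filler_dropped(self, baritosis_tbox):
        d = CandidateDefinition(
            "Baritosis",
            frozenset(),
            frozenset({("Causative_agent", "Dust"), ("Causative_agent", "Barium_dust")}),
        )
        simplified = simplify_definition(d, baritosis_tbox)
        assert simplified.existentials == {("Causative_agent", "Barium_dust")}

    def test_minimal_definition_unchanged_and_idempotent(self, baritosis_tbox):
        d = CandidateDefinition(
            "Baritosis",
            frozenset({"Pneumoconiosis"}),
            frozenset({("Causative_agent", "Barium_dust")}),
        )
        once = simplify_definition(d, baritosis_tbox)
        assert once == d
        assert simplify_definition(once, baritosis_tbox) == once

    def test_entailed_consequences_preserved(self, baritosis_tbox):
        from eldef.ontology import Axiom, TBox

        d = CandidateDefinition(
            "Pneumoconiosis",
            frozenset(),
            frozenset({("Causative_agent", "Dust"), ("Causative_agent", "Barium_dust")}),
        )
        simplified = simplify_definition(d, baritosis_tbox)

        def consequences(defn):
            tbox = TBox(
                concepts=dict(baritosis_tbox.concepts),
                roles=dict(baritosis_tbox.roles),
                axioms=list(baritosis_tbox.axioms)
                + [Axiom(defn.subject, defn.named_parents, defn.existentials)],
            )
            return {
                t for t in inferred_relationship_base(tbox).triples
                if t.subject == defn.subject
            }

        assert consequences(d) == consequences(simplified)


class TestDefPre:
    def test_inferred_candidate_scores_as_correct(self, baritosis_tbox):
        # not explicitly asserted, but entailed via the filler's superclass
        report = defpre(
            {"Baritosis": [RelTriple("Baritosis", "Causative_agent", "Dust")]},
            baritosis_tbox,
        )
        assert report.global_precision == 1.0

    def test_half_right_candidates(self, baritosis_tbox):
        from eldef.ontology import Role, TBox

        tbox = TBox(
            concepts=dict(baritosis_tbox.concepts),
            roles={**baritosis_tbox.roles, "Finding_site": Role("Finding_site", "fs")},
            axioms=list(baritosis_tbox.axioms),
        )
        report = defpre(
            {
                "Baritosis": [
                    RelTriple("Baritosis", "Causative_agent", "Dust"),
                    RelTriple("Baritosis", "Finding_site", "Dust"),
                ]
            },
            tbox,
        )
        assert report.global_precision == 0.5
        assert report.macro_precision == 0.5

    def test_zero_precision_concept_counted_in_macro(self, baritosis_tbox):
        report = defpre(
            {
                "Baritosis": [RelTriple("Baritosis", "Causative_agent", "Barium_dust")],
                "Dust": [RelTriple("Dust", "Causative_agent", "Baritosis")],
            },
            baritosis_tbox,
        )
        assert report.n_zero_precision == 1
        assert report.macro_precision == pytest.approx(0.5)
        assert report.macro_precision_nonzero == pytest.approx(1.0)

    def test_explicit_candidates_give_precision_one(self, baritosis_tbox):
        from eldef.ontology import explicit_relationship_base

        exp = explicit_relationship_base(baritosis_tbox)
        by_subject = {}
        for t in exp:
            by_subject.setdefault(t.subject, []).append(t)
        report = defpre(by_subject, baritosis_tbox)
        assert report.global_precision == 1.0
        assert report.macro_precision == 1.0

    def test_unresolvable_candidate_scored_wrong(self, baritosis_tbox):
        report = defpre(
            {"Baritosis": [RelTriple("Baritosis", "Causative_agent", "Unknown_thing")]},
            baritosis_tbox,
        )
        assert report.global_precision == 0.0

    def test_monotone_under_reference_growth(self, baritosis_tbox):
        from eldef.ontology import Axiom, Role, TBox

        candidates = {
            "Baritosis": [
                RelTriple("Baritosis", "Causative_agent", "Dust"),
                RelTriple("Baritosis", "Finding_site", "Dust"),
            ]
        }
        small = TBox(
            concepts=dict(baritosis_tbox.concepts),
            roles={**baritosis_tbox.roles, "Finding_site": Role("Finding_site", "fs")},
            axioms=list(baritosis_tbox.axioms),
        )
        grown = TBox(
            concepts=dict(small.concepts),
            roles=dict(small.roles),
            axioms=list(small.axioms)
            + [Axiom("Baritosis", frozenset(), frozenset({("Finding_site", "Dust")}))],
        )
        r_small = defpre(candidates, small)
        r_grown = defpre(candidates, grown)
        assert r_grown.global_precision >= r_small.global_precision
        assert r_grown.macro_precision >= r_small.macro_precision


def test_render_definition_readable():
    d = CandidateDefinition(
        "Baritosis",
        frozenset({"Pneumoconiosis"}),
        frozenset({("Causative_agent", "Barium_dust")}),
    )
    assert render_definition(d) == (
        "Baritosis SubClassOf Pneumoconiosis and (Causative_agent some Barium_dust)"
    )
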