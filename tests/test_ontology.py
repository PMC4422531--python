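"""Unit and property tests for the restricted-EL reasoner and TBox I/O."""

import numpy as np
import pytest

from eldef.ontology import (
    Axiom,
    Concept,
    OntologyError,
    RelTriple,
    Role,
    TBox,
    TBoxLoadError,
    UnknownIdError,
    entails_triple,
    explicit_relationship_base,
    inferred_relationship_base,
    parse_tbox,
    read_triples,
    role_subsumes,
    subsumes,
    write_tbox,
    write_triples,
)

from conftest import oracle_inferred, random_tbox


class TestParseTBox:
    def _write(self, tmp_path, concepts, roles, axioms):
        (tmp_path / "c.tsv").write_text(concepts)
        (tmp_path / "r.tsv").write_text(roles)
        (tmp_path / "a.tsv").write_text(axioms)
        return tmp_path / "c.tsv", tmp_path / "r.tsv", tmp_path / "a.tsv"

    def test_worked_fixture(self, tmp_path):
        files = self._write(
            tmp_path,
            "Baritosis\tBaritosis\tdisorder\n"
            "Pneumoconiosis\tPneumoconiosis\tdisorder\n"
            "Barium_dust\tbarium dust\tsubstance\n"
            "Dust\tdust\tsubstance\n",
            "Causative_agent\tcausative agent\n",
            "Baritosis\tPneumoconiosis\tCausative_agent:Barium_dust\n"
            "Barium_dust\tDust\t\n",
        )
        tbox = parse_tbox(*files)
        assert len(tbox.concepts) == 4
        assert len(tbox.roles) == 1
        assert len(tbox.axioms) == 2

    def test_empty_axioms_file(self, tmp_path):
        files = self._write(tmp_path, "A\ta\tt\n", "", "# no axioms\n")
        tbox = parse_tbox(*files)
        assert len(tbox.concepts) == 1 and not tbox.axioms

    def test_undeclared_concept_is_load_error(self, tmp_path):
        files = self._write(tmp_path, "A\ta\tt\n", "R\tr\n", "A\tGhost\t\n")
        with pytest.raises(TBoxLoadError, match="Ghost"):
            parse_tbox(*files)

    def test_equivalence_axiom_rejected(self, tmp_path):
        files = self._write(
            tmp_path, "A\ta\tt\nB\tb\tt\n", "", "A\tB\t\tequivalentto\n"
        )
        with pytest.raises(TBoxLoadError, match="quivalence"):
            parse_tbox(*files)

    def test_taxonomy_cycle_rejected(self, tmp_path):
        files = self._write(
            tmp_path, "A\ta\tt\nB\tb\tt\n", "", "A\tB\t\nB\tA\t\n"
        )
        with pytest.raises(OntologyError):
            parse_tbox(*files)

    def test_roundtrip(self, tmp_path, baritosis_tbox):
        paths = (tmp_path / "c.tsv", tmp_path / "r.tsv", tmp_path / "a.tsv")
        write_tbox(baritosis_tbox, *paths)
        again = parse_tbox(*paths)
        assert again.concepts == baritosis_tbox.concepts
        assert again.roles == baritosis_tbox.roles
        assert set(again.axioms) == set(baritosis_tbox.axioms)


class TestSubsumption:
    def test_taxonomic_link(self, baritosis_tbox):
        assert subsumes(baritosis_tbox, "Dust", "Barium_dust")

    def test_reflexive(self, baritosis_tbox):
        assert subsumes(baritosis_tbox, "Baritosis", "Baritosis")

    def test_direction_matters(self, baritosis_tbox):
        assert not subsumes(baritosis_tbox, "Barium_dust", "Dust")

    def test_unknown_id(self, baritosis_tbox):
        with pytest.raises(UnknownIdError):
            subsumes(baritosis_tbox, "Dust", "Nope")

    def test_transitive_on_random_tboxes(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            tbox = random_tbox(rng)
            cids = list(tbox.concepts)
            for a in cids:
                for b in cids:
                    for c in cids:
                        if subsumes(tbox, a, b) and subsumes(tbox, b, c):
                            assert subsumes(tbox, a, c)


class TestRoleSubsumption:
    def test_reflexive_flat(self, baritosis_tbox):
        assert role_subsumes(baritosis_tbox, "Causative_agent", "Causative_agent")

    def test_single_edge_and_direction(self):
        tbox = TBox(
            concepts={"A": Concept("A", "a", "t")},
            roles={"R2": Role("R2", "r2"), "R1": Role("R1", "r1", parent="R2")},
            axioms=[Axiom("A", frozenset(), frozenset({("R1", "A")}))],
        )
        assert role_subsumes(tbox, "R2", "R1")
        assert not role_subsumes(tbox, "R1", "R2")


class TestRelationshipBases:
    def test_explicit_of_fixture(self, baritosis_tbox):
        rb = explicit_relationship_base(baritosis_tbox)
        assert rb.triples == {RelTriple("Baritosis", "Causative_agent", "Barium_dust")}
        assert rb.provenance == "explicit"

    def test_taxonomic_only_tbox_gives_empty_base(self):
        tbox = TBox(
            concepts={"A": Concept("A", "a", "t"), "B": Concept("B", "b", "t")},
            roles={},
            axioms=[Axiom("A", frozenset({"B"}), frozenset())],
        )
        assert not explicit_relationship_base(tbox).triples

    def test_shared_existential_deduplicated(self):
        tbox = TBox(
            concepts={"A": Concept("A", "a", "t"), "B": Concept("B", "b", "t")},
            roles={"R": Role("R", "r")},
            axioms=[
                Axiom("A", frozenset(), frozenset({("R", "B")})),
                Axiom("A", frozenset({"B"}), frozenset({("R", "B")})),
            ],
        )
        assert len(explicit_relationship_base(tbox)) == 1

    def test_inferred_contains_generalised_filler(self, baritosis_tbox):
        inf = inferred_relationship_base(baritosis_tbox)
        assert RelTriple("Baritosis", "Causative_agent", "Dust") in inf

    def test_inferred_full_closure_on_fixture(self, baritosis_tbox):
        inf = inferred_relationship_base(baritosis_tbox)
        assert inf.triples == {
            RelTriple("Baritosis", "Causative_agent", "Barium_dust"),
            RelTriple("Baritosis", "Causative_agent", "Dust"),
        }

    def test_inferred_invariant_under_axiom_order(self, baritosis_tbox):
        reversed_tbox = TBox(
            concepts=dict(baritosis_tbox.concepts),
            roles=dict(baritosis_tbox.roles),
            axioms=list(reversed(baritosis_tbox.axioms)),
        )
        assert (
            inferred_relationship_base(baritosis_tbox).triples
            == inferred_relationship_base(reversed_tbox).triples
        )


class TestEntailment:
    def test_inferred_triple_entailed(self, baritosis_tbox):
        assert entails_triple(
            baritosis_tbox, RelTriple("Baritosis", "Causative_agent", "Dust")
        )

    def test_reversed_triple_not_entailed(self, baritosis_tbox):
        assert not entails_triple(
            baritosis_tbox, RelTriple("Dust", "Causative_agent", "Baritosis")
        )

    def test_explicit_triple_entailed(self, baritosis_tbox):
        assert entails_triple(
            baritosis_tbox, RelTriple("Baritosis", "Causative_agent", "Barium_dust")
        )

    def test_entailment_matches_materialised_base(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            tbox = random_tbox(rng)
            inf = inferred_relationship_base(tbox)
            for a in tbox.concepts:
                for r in tbox.roles:
                    for b in tbox.concepts:
                        t = RelTriple(a, r, b)
                        assert entails_triple(tbox, t) == (t in inf)


class TestOracleAgreement:
    def test_reasoner_equals_bruteforce_oracle(self):
        """Closure-rule reasoner agrees exactly with path-enumeration saturation."""
        rng = np.random.default_rng(101)
        for _ in range(50):
            tbox = random_tbox(rng)
            assert (
                inferred_relationship_base(tbox).triples
                == oracle_inferred(tbox).triples
            )

    def test_monotonicity_explicit_subset_of_inferred(self):
        rng = np.random.default_rng(202)
        for _ in range(50):
            tbox = random_tbox(rng)
            assert explicit_relationship_base(tbox).triples <= (
                inferred_relationship_base(tbox).triples
            )


def test_triple_file_roundtrip(tmp_path, baritosis_tbox):
    rb = inferred_relationship_base(baritosis_tbox)
    path = tmp_path / "triples.txt"
    write_triples(rb, path)
    assert path.read_text().splitlines()[0].count("|") == 2
    assert read_triples(path).triples == rb.triples
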