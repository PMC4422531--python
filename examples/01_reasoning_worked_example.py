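"""Build a tiny terminology by hand and reason over it.

The terminology says: Baritosis is a pneumoconiosis caused by barium dust,
and barium dust is a kind of dust.  The explicit relationship base reads
triples straight off the axioms; the inferred base closes them under
subsumption, which is why `Baritosis|Causative_agent|Dust` holds without
ever being written down.
"""

from eldef import (
    Axiom, Concept, RelTriple, Role, TBox,
    entails_triple, explicit_relationship_base, inferred_relationship_base,
    subsumes,
)

tbox = TBox(
    concepts={
        "Baritosis": Concept("Baritosis", "Baritosis", "disorder"),
        "Pneumoconiosis": Concept("Pneumoconiosis", "Pneumoconiosis", "disorder"),
        "Barium_dust": Concept("Barium_dust", "barium dust", "substance"),
        "Dust": Concept("Dust", "dust", "substance"),
    },
    roles={"Causative_agent": Role("Causative_agent", "causative agent")},
    axioms=[
        Axiom("Baritosis", frozenset({"Pneumoconiosis"}),
              frozenset({("Causative_agent", "Barium_dust")})),
        Axiom("Barium_dust", frozenset({"Dust"}), frozenset()),
    ],
)

print("Dust subsumes Barium_dust:", subsumes(tbox, "Dust", "Barium_dust"))

exp = explicit_relationship_base(tbox)
inf = inferred_relationship_base(tbox)
print("explicit base:", [str(t) for t in exp])
print("inferred base:", [str(t) for t in inf])

candidate = RelTriple("Baritosis", "Causative_agent", "Dust")
print(f"entails {candidate}?", entails_triple(tbox, candidate))
# The inferred base is a strict superset of the explicit one: reasoning
# turns 1 asserted relationship into 2 usable ones.
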