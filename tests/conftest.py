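"""Shared fixtures: the four-concept worked example, a random-TBox
generator and an independent brute-force entailment oracle."""

from __future__ import annotations

import numpy as np
import pytest

from eldef.ontology import (
    Axiom,
    Concept,
    RelTriple,
    RelationshipBase,
    Role,
    TBox,
)


@pytest.fixture
def baritosis_tbox() -> TBox:
    """Baritosis ⊑ Pneumoconiosis ⊓ ∃Causative_agent.Barium_dust; Barium_dust ⊑ Dust."""
    concepts = {
        "Baritosis": Concept("Baritosis", "Baritosis", "disorder"),
        "Pneumoconiosis": Concept("Pneumoconiosis", "Pneumoconiosis", "disorder"),
        "Barium_dust": Concept("Barium_dust", "barium dust", "substance"),
        "Dust": Concept("Dust", "dust", "substance"),
    }
    roles = {"Causative_agent": Role("Causative_agent", "causative agent")}
    axioms = [
        Axiom(
            "Baritosis",
            frozenset({"Pneumoconiosis"}),
            frozenset({("Causative_agent", "Barium_dust")}),
        ),
        Axiom("Barium_dust", frozenset({"Dust"}), frozenset()),
    ]
    return TBox(concepts=concepts, roles=roles, axioms=axioms)


TABLE_SENTENCE = "Baritosis is pneumoconiosis caused by barium dust"
TABLE_MENTIONS = (("Baritosis", 0, 9), ("Barium_dust", 38, 49))


# ---------------------------------------------------------------------------
# Random TBoxes and the brute-force oracle
# ---------------------------------------------------------------------------


def random_tbox(
    rng: np.random.Generator,
    max_concepts: int = 15,
    max_roles: int = 3,
    max_existentials: int = 2,
) -> TBox:
    """A small random TBox: DAG taxonomy, optional role hierarchy, flat axioms."""
    n_concepts = int(rng.integers(2, max_concepts + 1))
    n_roles = int(rng.integers(1, max_roles + 1))
    cids = [f"C{i}" for i in range(n_concepts)]
    concepts = {c: Concept(c, c.lower(), f"t{int(rng.integers(3))}") for c in cids}
    roles = {}
    for i in range(n_roles):
        parent = f"R{int(rng.integers(i))}" if i > 0 and rng.random() < 0.4 else None
        roles[f"R{i}"] = Role(f"R{i}", f"r{i}", parent)

    axioms = []
    for i, cid in enumerate(cids):
        parents = set()
        if i > 0 and rng.random() < 0.8:
            n_parents = 2 if (i > 1 and rng.random() < 0.3) else 1
            parents = {
                cids[int(j)] for j in rng.choice(i, size=min(n_parents, i), replace=False)
            }
        existentials = set()
        for _ in range(int(rng.integers(0, max_existentials + 1))):
            if rng.random() < 0.5:
                r = f"R{int(rng.integers(n_roles))}"
                b = cids[int(rng.integers(n_concepts))]
                existentials.add((r, b))
        if parents or existentials:
            axioms.append(Axiom(cid, frozenset(parents), frozenset(existentials)))
    return TBox(concepts=concepts, roles=roles, axioms=axioms)


def _reaches_up(edges: dict[str, set[str]], start: str, goal: str) -> bool:
    """Depth-first path enumeration from ``start`` upward to ``goal``."""
    if start == goal:
        return True
    stack, seen = [start], set()
    while stack:
        node = stack.pop()
        if node in seen:
            continue
        seen.add(node)
        for parent in edges.get(node, ()):
            if parent == goal:
                return True
            stack.append(parent)
    return False


def oracle_inferred(tbox: TBox) -> RelationshipBase:
    """Brute-force oracle for the inferred relationship base.

    Enumerates every (A, R, B) and tests entailment by depth-first path
    search over raw parent edges — no closure precomputation, no shared
    code with the library reasoner.
    """
    concept_edges: dict[str, set[str]] = {}
    for ax in tbox.axioms:
        concept_edges.setdefault(ax.subject, set()).update(ax.named_parents)
    role_edges: dict[str, set[str]] = {
        r.id: ({r.parent} if r.parent else set()) for r in tbox.roles.values()
    }
    asserted = [
        (ax.subject, r, b) for ax in tbox.axioms for r, b in ax.existentials
    ]
    triples = set()
    for a in tbox.concepts:
        for r in tbox.roles:
            for b in tbox.concepts:
                for s, r2, b2 in asserted:
                    if (
                        _reaches_up(concept_edges, a, s)
                        and _reaches_up(role_edges, r2, r)
                        and _reaches_up(concept_edges, b2, b)
                    ):
                        triples.add(RelTriple(a, r, b))
                        break
    return RelationshipBase(frozenset(triples), provenance="inferred")
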