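"""Seeded synthetic terminologies and definitional corpora.

The generator emulates the statistical structure that a distant-supervision
definition-learning pipeline exploits in real terminologies and texts:

* a taxonomy tree of named concepts, each with exactly one semantic type;
* a handful of roles, each with a (domain-type, range-type) signature;
  ``type_overlap`` (θ) controls how many roles share a signature — at
  θ=0 every role has a distinct signature (types alone identify the
  relation, as for the disjointly-typed disorder relations of a curated
  clinical terminology), at θ=1 all roles share one signature (types carry
  no signal);
* flat primitive-definition axioms whose existentials connect
  type-compatible concepts — these are the ground-truth relationships;
* templated definitional sentences ``<subject label> <template> <object
  label>`` where each role owns a set of short English-like lexical
  templates; ``pattern_noise`` is the probability that a sentence is
  verbalised with a template borrowed from a different role, degrading the
  lexical (but never the type) channel.

All outputs are pure functions of :class:`SimConfig` — the same seed gives
byte-identical artifacts.  Concept labels are pronounceable pseudo-Latin
words so that character n-grams behave as on real text.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .alignment import RelationInstance
from .corpus import AnnotatedSentence, Corpus, Mention
from .ontology import (
    Axiom,
    Concept,
    RelationshipBase,
    RelTriple,
    Role,
    TBox,
    explicit_relationship_base,
    inferred_relationship_base,
)

__all__ = ["SimConfig", "simulate_tbox", "simulate_corpus", "simulate_benchmark"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic benchmark.

    ``type_overlap`` (θ) is the fraction by which role-signature diversity
    is collapsed: the number of distinct (domain, range) signatures is
    ``max(1, round(n_roles - θ * (n_roles - 1)))``, so θ=0 gives all-distinct
    and θ=1 a single shared signature.  ``pattern_noise`` is the
    probability that a sentence uses a lexical template of a different
    role.  ``triples_per_role`` bounds the number of ground-truth
    relationships sampled per role.
    """

    seed: int = 0
    n_concepts: int = 60
    taxonomy_branching: float = 3.0
    n_roles: int = 3
    n_types: int = 6
    type_overlap: float = 0.0
    patterns_per_role: int = 4
    pattern_noise: float = 0.1
    sentences_per_triple: int = 2
    triples_per_role: int = 20

    def __post_init__(self) -> None:
        if min(self.n_concepts, self.n_roles, self.n_types,
               self.patterns_per_role, self.sentences_per_triple,
               self.triples_per_role) < 1:
            raise ValueError("all counts must be >= 1")
        if self.taxonomy_branching < 1:
            raise ValueError("taxonomy_branching must be >= 1")
        if not (0.0 <= self.type_overlap <= 1.0):
            raise ValueError("type_overlap must be in [0, 1]")
        if not (0.0 <= self.pattern_noise <= 1.0):
            raise ValueError("pattern_noise must be in [0, 1]")


_SYLLABLES = [
    "ba", "ri", "to", "sis", "pneu", "mo", "co", "ni", "der", "ma",
    "ti", "lo", "gra", "nu", "pa", "thy", "car", "di", "os", "teo",
    "fi", "bro", "ne", "phro", "my", "al", "gi", "he", "pa", "tox",
]

# Short definitional connectives; each role gets its own disjoint slice.
_TEMPLATE_POOL = [
    "is caused by", "results from", "is found in", "affects the",
    "is associated with", "arises from", "occurs in", "is due to",
    "involves the", "is characterized by", "develops after exposure to",
    "is located in", "is triggered by", "spreads to", "originates in",
    "damages the", "is a consequence of", "manifests in",
    "is attributed to", "presents within the", "stems from",
    "is confined to", "follows contact with", "appears in",
]


def _make_label(rng: np.random.Generator, used: set[str]) -> str:
    for _ in range(1000):
        k = int(rng.integers(2, 5))
        word = "".join(rng.choice(_SYLLABLES) for _ in range(k))
        if word not in used and 4 <= len(word) <= 18:
            used.add(word)
            return word
    raise RuntimeError("could not generate a fresh label")


def _role_signatures(config: SimConfig, rng: np.random.Generator) -> list[tuple[int, int]]:
    """One (domain-type, range-type) pair per role, collapsed per θ."""
    n_distinct = max(1, round(config.n_roles - config.type_overlap * (config.n_roles - 1)))
    all_pairs = list(itertools.product(range(config.n_types), repeat=2))
    if n_distinct > len(all_pairs):
        raise ValueError(
            f"type_overlap={config.type_overlap} needs {n_distinct} distinct "
            f"(domain, range) signatures but only {len(all_pairs)} exist for "
            f"{config.n_types} types"
        )
    chosen = [all_pairs[i] for i in rng.choice(len(all_pairs), size=n_distinct,
                                               replace=False)]
    return [chosen[i % n_distinct] for i in range(config.n_roles)]


def simulate_tbox(config: SimConfig) -> TBox:
    """Random taxonomy, typed concepts, signed roles and flat axioms.

    The taxonomy is grown breadth-first with Poisson(``taxonomy_branching``)
    children per node.  Concept types are assigned round-robin (every type
    is populated) and ground-truth existential axioms connect
    type-compatible (domain, range) concept pairs of each role.
    """
    rng = np.random.default_rng(config.seed)
    signatures = _role_signatures(config, rng)

    used_labels: set[str] = set()
    concept_ids = [f"C{i:03d}" for i in range(config.n_concepts)]
    labels = [_make_label(rng, used_labels) for _ in concept_ids]
    type_names = [f"type{t}" for t in range(config.n_types)]
    # round-robin over a shuffled concept order: every type populated
    order = rng.permutation(config.n_concepts)
    concept_type = {}
    for pos, ci in enumerate(order):
        concept_type[concept_ids[ci]] = type_names[pos % config.n_types]

    concepts = {
        cid: Concept(cid, labels[i], concept_type[cid])
        for i, cid in enumerate(concept_ids)
    }
    roles = {
        f"R{i}": Role(f"R{i}", f"relation_{i}") for i in range(config.n_roles)
    }

    # breadth-first taxonomy tree
    parent: dict[str, str] = {}
    queue = [concept_ids[0]]
    next_child = 1
    while next_child < config.n_concepts:
        node = queue.pop(0) if queue else concept_ids[0]
        k = max(1, int(rng.poisson(config.taxonomy_branching)))
        for _ in range(k):
            if next_child >= config.n_concepts:
                break
            child = concept_ids[next_child]
            parent[child] = node
            queue.append(child)
            next_child += 1

    axioms = [
        Axiom(child, frozenset({p}), frozenset()) for child, p in sorted(parent.items())
    ]

    by_type: dict[str, list[str]] = {}
    for cid in concept_ids:
        by_type.setdefault(concept_type[cid], []).append(cid)

    for ri in range(config.n_roles):
        rid = f"R{ri}"
        dom_t, ran_t = signatures[ri]
        subjects = by_type[type_names[dom_t]]
        fillers = by_type[type_names[ran_t]]
        pairs = [(s, f) for s in subjects for f in fillers if s != f]
        if not pairs:
            raise ValueError(f"no type-compatible pairs for role {rid}")
        n_pick = min(config.triples_per_role, len(pairs))
        picked = rng.choice(len(pairs), size=n_pick, replace=False)
        for idx in sorted(picked):
            s, f = pairs[idx]
            axioms.append(Axiom(s, frozenset(), frozenset({(rid, f)})))

    return TBox(concepts=concepts, roles=roles, axioms=axioms)


def _role_templates(config: SimConfig) -> dict[str, list[str]]:
    """Disjoint per-role template slices; extended programmatically if needed."""
    pool = list(_TEMPLATE_POOL)
    needed = config.n_roles * config.patterns_per_role
    i = 0
    while len(pool) < needed:
        pool.append(f"{_TEMPLATE_POOL[i % len(_TEMPLATE_POOL)]} the region of")
        i += 1
    return {
        f"R{ri}": pool[ri * config.patterns_per_role : (ri + 1) * config.patterns_per_role]
        for ri in range(config.n_roles)
    }


def simulate_corpus(
    tbox: TBox, rb: RelationshipBase, config: SimConfig
) -> tuple[Corpus, list[RelationInstance]]:
    """Templated definitional sentences for the triples of ``rb``.

    Each triple yields ``sentences_per_triple`` sentences of the form
    ``<subject label> <template> <object label>`` with exact gold mentions.
    With probability ``pattern_noise`` the template is drawn from a
    different role, so the between-string misleads while the gold label
    (returned alongside) stays correct.
    """
    rng = np.random.default_rng(config.seed + 1)
    templates = _role_templates(config)
    other_roles = {
        r: [q for q in templates if q != r] for r in templates
    }
    sentences: list[AnnotatedSentence] = []
    gold: list[RelationInstance] = []
    triples = sorted(rb.triples, key=lambda t: (t.subject, t.role, t.object))
    for triple in triples:
        subj_label = tbox.concepts[triple.subject].label
        obj_label = tbox.concepts[triple.object].label
        for _ in range(config.sentences_per_triple):
            role_for_text = triple.role
            if other_roles[triple.role] and rng.random() < config.pattern_noise:
                role_for_text = other_roles[triple.role][
                    int(rng.integers(len(other_roles[triple.role])))
                ]
            template = templates[role_for_text][
                int(rng.integers(len(templates[role_for_text])))
            ]
            text = f"{subj_label} {template} {obj_label}."
            m1 = Mention(triple.subject, 0, len(subj_label))
            m2 = Mention(
                triple.object,
                len(subj_label) + 1 + len(template) + 1,
                len(subj_label) + 1 + len(template) + 1 + len(obj_label),
            )
            sentences.append(AnnotatedSentence(text, (m1, m2), source="synthetic"))
            gold.append(
                RelationInstance(
                    sentence_index=len(sentences) - 1,
                    subject=triple.subject,
                    object=triple.object,
                    between=template.lower(),
                    subject_type=tbox.semantic_type(triple.subject),
                    object_type=tbox.semantic_type(triple.object),
                    label=triple.role,
                )
            )
    return Corpus(sentences), gold


def simulate_benchmark(
    config: SimConfig = SimConfig(),
) -> tuple[TBox, Corpus, list[RelationInstance], RelationshipBase, RelationshipBase]:
    """One coherent end-to-end fixture.

    Returns ``(tbox, corpus, gold_instances, exp_rb, inf_rb)`` where the
    corpus verbalises exactly the explicit relationships, the gold labels
    are members of ``exp_rb`` and ``exp_rb ⊆ inf_rb`` by construction.
    """
    tbox = simulate_tbox(config)
    exp_rb = explicit_relationship_base(tbox)
    inf_rb = inferred_relationship_base(tbox)
    corpus, gold = simulate_corpus(tbox, exp_rb, config)
    return tbox, corpus, gold, exp_rb, inf_rb
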