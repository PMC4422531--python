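"""Assembly of relationship triples into EL axioms and definition scoring.

Predicted triples sharing a subject are folded into one flat primitive
definition::

    A|R|B                   ->  A ⊑ ∃R.B
    {A|R_i|B_i}             ->  A ⊑ ⊓_i ∃R_i.B_i

with triples of a designated is-a role contributing named-parent conjuncts
instead of existentials.  Generated definitions always use the inclusion
operator, never equivalence.

Definition precision (DefPre) scores a multiset of candidate triples
against a reference terminology: a candidate ``A|R|B`` counts as correct
iff the reference entails ``A ⊑ ∃R.B`` — so a candidate may be correct
without being explicitly asserted (e.g. a filler that generalises the
asserted one).  Both the global triple-level precision and per-concept
averages are reported; concepts whose candidate triples are all wrong
("zero-precision" concepts) are counted and the per-concept mean is given
both including and excluding them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .ontology import (
    RelTriple,
    TBox,
    entails_triple,
    subsumes,
)

__all__ = [
    "CandidateDefinition",
    "DefPreReport",
    "AssemblyError",
    "assemble_definition",
    "read_back_triples",
    "simplify_definition",
    "defpre",
    "render_definition",
    "write_definitions",
]

logger = logging.getLogger(__name__)


class AssemblyError(ValueError):
    """Invalid input to definition assembly."""


@dataclass(frozen=True)
class CandidateDefinition:
    """A flat EL inclusion axiom proposed for ``subject``."""

    subject: str
    named_parents: frozenset[str] = frozenset()
    existentials: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "named_parents", frozenset(self.named_parents))
        object.__setattr__(self, "existentials", frozenset(self.existentials))
        if not self.named_parents and not self.existentials:
            raise AssemblyError(
                f"definition for {self.subject!r} must have at least one conjunct"
            )


def assemble_definition(
    subject: str,
    triples: Iterable[RelTriple],
    isa_role: str | None = None,
) -> CandidateDefinition:
    """Fold triples for one subject into a single flat inclusion axiom.

    Triples whose role equals ``isa_role`` become named-parent conjuncts;
    all others become existential conjuncts.  Duplicates collapse.
    """
    triples = list(triples)
    if not triples:
        raise AssemblyError(f"no triples to assemble for {subject!r}")
    bad = [t for t in triples if t.subject != subject]
    if bad:
        raise AssemblyError(
            f"triples with foreign subject passed for {subject!r}: {bad[0]}"
        )
    parents = frozenset(t.object for t in triples if t.role == isa_role)
    existentials = frozenset(
        (t.role, t.object) for t in triples if t.role != isa_role
    )
    return CandidateDefinition(subject, parents, existentials)


def read_back_triples(
    definition: CandidateDefinition, isa_role: str | None = None
) -> frozenset[RelTriple]:
    """Inverse of :func:`assemble_definition` (up to deduplication)."""
    triples = {
        RelTriple(definition.subject, r, b) for r, b in definition.existentials
    }
    if definition.named_parents:
        if isa_role is None:
            logger.warning(
                "definition for %r has named parents but no isa_role given; "
                "parent conjuncts are dropped from the triple view",
                definition.subject,
            )
        else:
            triples.update(
                RelTriple(definition.subject, isa_role, p)
                for p in definition.named_parents
            )
    return frozenset(triples)


def simplify_definition(
    definition: CandidateDefinition, tbox: TBox
) -> CandidateDefinition:
    """Prune conjuncts subsumed by more specific ones (idempotent).

    A named parent is dropped when another named parent is subsumed by it;
    an existential ``(R, B)`` is dropped when another ``(R, B')`` with
    ``B' ⊑ B`` exists.  The entailed consequences of the definition are
    unchanged.
    """
    parents = set(definition.named_parents)
    for p in sorted(definition.named_parents):
        others = parents - {p}
        if any(subsumes(tbox, p, q) for q in others):
            parents.discard(p)
    existentials = set(definition.existentials)
    for r, b in sorted(definition.existentials):
        others = existentials - {(r, b)}
        if any(r2 == r and b2 != b and subsumes(tbox, b, b2) for r2, b2 in others):
            existentials.discard((r, b))
    return CandidateDefinition(definition.subject, frozenset(parents),
                               frozenset(existentials))


@dataclass
class DefPreReport:
    """Definition-precision scores for a set of per-concept candidates.

    ``global_precision`` is entailed candidates over all candidates.
    ``macro_precision`` averages per-concept precision over concepts with
    at least one candidate (zero-precision concepts included);
    ``macro_precision_nonzero`` excludes them.
    """

    global_precision: float
    macro_precision: float
    macro_precision_nonzero: float
    per_concept: dict[str, tuple[int, int, float]]  # (n_candidates, n_entailed, precision)
    n_zero_precision: int
    whole_definition_correct: dict[str, bool]

    def to_json(self) -> str:
        obj = {
            "global_precision": self.global_precision,
            "macro_precision": self.macro_precision,
            "macro_precision_nonzero": self.macro_precision_nonzero,
            "n_zero_precision": self.n_zero_precision,
            "per_concept": {
                c: {"n_candidates": n, "n_entailed": k, "precision": p}
                for c, (n, k, p) in sorted(self.per_concept.items())
            },
            "whole_definition_correct": dict(sorted(self.whole_definition_correct.items())),
        }
        return json.dumps(obj, indent=2, sort_keys=True)


def defpre(
    candidates: Mapping[str, Iterable[RelTriple]],
    reference: TBox,
) -> DefPreReport:
    """Score candidate triples against a reference terminology by entailment.

    A candidate referencing an id unknown to the reference scores as not
    entailed (with a warning) — the behaviour wanted for out-of-vocabulary
    predictions.
    """
    per_concept: dict[str, tuple[int, int, float]] = {}
    whole_ok: dict[str, bool] = {}
    total, entailed_total = 0, 0
    for concept, triples in candidates.items():
        triples = list(triples)
        n = len(triples)
        k = 0
        for t in triples:
            try:
                if entails_triple(reference, t):
                    k += 1
            except KeyError:
                logger.warning("candidate %s has unresolvable ids; scored as wrong", t)
        total += n
        entailed_total += k
        per_concept[concept] = (n, k, k / n if n else 0.0)
        whole_ok[concept] = n > 0 and k == n

    scored = {c: p for c, (n, _k, p) in per_concept.items() if n > 0}
    nonzero = [p for p in scored.values() if p > 0]
    return DefPreReport(
        global_precision=entailed_total / total if total else 0.0,
        macro_precision=sum(scored.values()) / len(scored) if scored else 0.0,
        macro_precision_nonzero=sum(nonzero) / len(nonzero) if nonzero else 0.0,
        per_concept=per_concept,
        n_zero_precision=sum(1 for p in scored.values() if p == 0.0),
        whole_definition_correct=whole_ok,
    )


def render_definition(definition: CandidateDefinition) -> str:
    """Human-readable rendering: ``A SubClassOf P and (R some B)``."""
    conjuncts = sorted(definition.named_parents)
    conjuncts += [f"({r} some {b})" for r, b in sorted(definition.existentials)]
    return f"{definition.subject} SubClassOf " + " and ".join(conjuncts)


def write_definitions(
    definitions: Iterable[CandidateDefinition],
    axioms_path: str | Path | None = None,
    text_path: str | Path | None = None,
) -> None:
    """Serialise definitions: TSV axiom dialect and/or human-readable text."""
    definitions = sorted(definitions, key=lambda d: d.subject)
    if axioms_path is not None:
        with open(axioms_path, "w", encoding="utf-8") as fh:
            for d in definitions:
                parents = ",".join(sorted(d.named_parents))
                exts = ",".join(f"{r}:{b}" for r, b in sorted(d.existentials))
                fh.write(f"{d.subject}\t{parents}\t{exts}\n")
    if text_path is not None:
        with open(text_path, "w", encoding="utf-8") as fh:
            for d in definitions:
                fh.write(render_definition(d) + "\n")
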