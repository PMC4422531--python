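"""Restricted-EL ontology model and reasoning.

The reasoning substrate mirrors the fragment of EL actually used by flat,
SNOMED CT-style primitive concept definitions: every axiom has the shape

    A  ⊑  P1 ⊓ ... ⊓ Pk ⊓ ∃R1.B1 ⊓ ... ⊓ ∃Rm.Bm

where all of ``A``, ``Pi``, ``Bj`` are *named* concepts and every ``Rj`` is a
named role.  Only inclusions (primitive definitions) are admitted —
equivalence axioms are rejected at load time.  Within this fragment,
subsumption between named concepts is exactly the reflexive-transitive
closure of the named-parent edges, and ``A ⊑ ∃R.B`` is entailed iff some
axiom subject ``A'`` above ``A`` carries an existential ``(R', B')`` with
``R'`` below ``R`` in the role hierarchy and ``B'`` below ``B`` in the
taxonomy.  These closure rules are complete for the fragment (no role
chains, nominals, bottom or general concept inclusions exist to interact),
and the test suite enforces agreement with a brute-force saturation oracle
rather than taking completeness on faith.

File dialect
------------
Three TSV files describe a TBox (UTF-8, ``#`` comments, blank lines
ignored):

* ``concepts.tsv`` — ``id<TAB>label<TAB>semantic_type``
* ``roles.tsv``    — ``id<TAB>label[<TAB>parent_id]``
* ``axioms.tsv``   — ``subject<TAB>parent_ids<TAB>existentials`` with
  comma-separated parent ids and comma-separated ``role:filler`` pairs;
  either of the last two columns may be empty, but not both.  An optional
  fourth column names the axiom operator and must denote inclusion
  (``subclassof`` / ``⊑``); equivalence is a load error.

Relationship triples are serialised one per line as ``A|R|B``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx

__all__ = [
    "Concept",
    "Role",
    "Axiom",
    "TBox",
    "RelTriple",
    "RelationshipBase",
    "OntologyError",
    "TBoxLoadError",
    "UnknownIdError",
    "parse_tbox",
    "subsumes",
    "role_subsumes",
    "explicit_relationship_base",
    "inferred_relationship_base",
    "entails_triple",
    "read_triples",
    "write_triples",
]


class OntologyError(ValueError):
    """Invalid ontology content (referential integrity, cycles, ...)."""


class TBoxLoadError(OntologyError):
    """Malformed TBox input file; message names the offending file/line."""


class UnknownIdError(KeyError):
    """A concept or role id was not found in the TBox."""


@dataclass(frozen=True)
class Concept:
    """A named concept with exactly one semantic type (as in SNOMED CT)."""

    id: str
    label: str
    semantic_type: str

    def __post_init__(self) -> None:
        if not self.id:
            raise OntologyError("concept id must be non-empty")
        if not self.semantic_type:
            raise OntologyError(f"concept {self.id!r}: semantic_type must be non-empty")


@dataclass(frozen=True)
class Role:
    """A named role (relation), optionally below a parent role."""

    id: str
    label: str
    parent: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise OntologyError("role id must be non-empty")


@dataclass(frozen=True)
class Axiom:
    """A flat primitive inclusion: subject ⊑ ⊓ parents ⊓ ⊓ ∃role.filler."""

    subject: str
    named_parents: frozenset[str] = frozenset()
    existentials: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "named_parents", frozenset(self.named_parents))
        object.__setattr__(self, "existentials", frozenset(self.existentials))
        if not self.named_parents and not self.existentials:
            raise OntologyError(
                f"axiom for {self.subject!r}: needs at least one parent or existential"
            )


@dataclass(frozen=True)
class RelTriple:
    """A relationship instance ``subject | role | object``."""

    subject: str
    role: str
    object: str

    def __str__(self) -> str:
        return f"{self.subject}|{self.role}|{self.object}"

    @classmethod
    def parse(cls, line: str) -> "RelTriple":
        parts = line.strip().split("|")
        if len(parts) != 3 or not all(parts):
            raise OntologyError(f"malformed triple line: {line!r}")
        return cls(*parts)


@dataclass(frozen=True)
class RelationshipBase:
    """A deduplicated set of relationship triples with provenance.

    ``provenance`` is one of ``explicit`` (read off axioms), ``inferred``
    (closed under entailment) or ``external`` (loaded from a file).
    """

    triples: frozenset[RelTriple]
    provenance: str = "external"

    def __post_init__(self) -> None:
        object.__setattr__(self, "triples", frozenset(self.triples))

    def __len__(self) -> int:
        return len(self.triples)

    def __contains__(self, triple: RelTriple) -> bool:
        return triple in self.triples

    def __iter__(self) -> Iterator[RelTriple]:
        return iter(sorted(self.triples, key=lambda t: (t.subject, t.role, t.object)))


@dataclass
class TBox:
    """A terminology: concepts, roles and flat primitive-inclusion axioms."""

    concepts: dict[str, Concept] = field(default_factory=dict)
    roles: dict[str, Role] = field(default_factory=dict)
    axioms: list[Axiom] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        """Check referential integrity and acyclicity; raise OntologyError."""
        for role in self.roles.values():
            if role.parent is not None and role.parent not in self.roles:
                raise OntologyError(
                    f"role {role.id!r}: unknown parent role {role.parent!r}"
                )
        for ax in self.axioms:
            if ax.subject not in self.concepts:
                raise OntologyError(f"axiom subject {ax.subject!r} not declared")
            for p in ax.named_parents:
                if p not in self.concepts:
                    raise OntologyError(
                        f"axiom for {ax.subject!r}: unknown parent concept {p!r}"
                    )
            for r, b in ax.existentials:
                if r not in self.roles:
                    raise OntologyError(f"axiom for {ax.subject!r}: unknown role {r!r}")
                if b not in self.concepts:
                    raise OntologyError(
                        f"axiom for {ax.subject!r}: unknown filler concept {b!r}"
                    )
        if not nx.is_directed_acyclic_graph(self._taxonomy_graph()):
            raise OntologyError("taxonomy (named-parent graph) contains a cycle")
        if not nx.is_directed_acyclic_graph(self._role_graph()):
            raise OntologyError("role hierarchy contains a cycle")

    # -- graphs -------------------------------------------------------------

    def _taxonomy_graph(self) -> nx.DiGraph:
        """Directed graph with an edge child -> parent per named-parent link."""
        g = nx.DiGraph()
        g.add_nodes_from(self.concepts)
        for ax in self.axioms:
            for p in ax.named_parents:
                g.add_edge(ax.subject, p)
        return g

    def _role_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.roles)
        for role in self.roles.values():
            if role.parent is not None:
                g.add_edge(role.id, role.parent)
        return g

    def merged_axioms(self) -> dict[str, tuple[frozenset[str], frozenset[tuple[str, str]]]]:
        """Conjuncts of all axioms per subject, unioned (logical merge)."""
        merged: dict[str, tuple[set[str], set[tuple[str, str]]]] = {}
        for ax in self.axioms:
            parents, exts = merged.setdefault(ax.subject, (set(), set()))
            parents.update(ax.named_parents)
            exts.update(ax.existentials)
        return {
            s: (frozenset(p), frozenset(e)) for s, (p, e) in sorted(merged.items())
        }

    def _require_concept(self, cid: str) -> None:
        if cid not in self.concepts:
            raise UnknownIdError(f"unknown concept id: {cid!r}")

    def _require_role(self, rid: str) -> None:
        if rid not in self.roles:
            raise UnknownIdError(f"unknown role id: {rid!r}")

    def semantic_type(self, cid: str) -> str:
        self._require_concept(cid)
        return self.concepts[cid].semantic_type

    def ancestors(self, cid: str) -> frozenset[str]:
        """All named concepts subsuming ``cid``, including itself."""
        self._require_concept(cid)
        return frozenset(nx.descendants(self._taxonomy_graph(), cid)) | {cid}

    def concept_descendants(self, cid: str) -> frozenset[str]:
        """All named concepts subsumed by ``cid``, including itself."""
        self._require_concept(cid)
        return frozenset(nx.ancestors(self._taxonomy_graph(), cid)) | {cid}

    def role_ancestors(self, rid: str) -> frozenset[str]:
        self._require_role(rid)
        return frozenset(nx.descendants(self._role_graph(), rid)) | {rid}


# ---------------------------------------------------------------------------
# Reasoning operations
# ---------------------------------------------------------------------------


def subsumes(tbox: TBox, ancestor: str, descendant: str) -> bool:
    """True iff ``descendant ⊑ ancestor`` via the named-parent closure.

    The relation is reflexive and transitive; it is the is-a relation of
    the taxonomy, e.g. ``subsumes(t, Dust, Barium_dust)``.
    """
    tbox._require_concept(ancestor)
    tbox._require_concept(descendant)
    return ancestor in tbox.ancestors(descendant)


def role_subsumes(tbox: TBox, ancestor: str, descendant: str) -> bool:
    """True iff ``descendant`` reaches ``ancestor`` via role-parent edges."""
    tbox._require_role(ancestor)
    tbox._require_role(descendant)
    return ancestor in tbox.role_ancestors(descendant)


def explicit_relationship_base(tbox: TBox) -> RelationshipBase:
    """Triples read directly off the axioms' existential conjuncts (ExpRB)."""
    triples = frozenset(
        RelTriple(ax.subject, r, b) for ax in tbox.axioms for r, b in ax.existentials
    )
    return RelationshipBase(triples, provenance="explicit")


def inferred_relationship_base(tbox: TBox) -> RelationshipBase:
    """All triples ``A|R|B`` with ``TBox ⊨ A ⊑ ∃R.B`` (InfRB).

    For every asserted existential ``A' ⊑ ∃R'.B'``, the entailed triples
    are the product of the descendants of ``A'``, the role-ancestors of
    ``R'`` and the ancestors of ``B'``.  Explicit triples are always a
    subset (monotonicity).
    """
    triples: set[RelTriple] = set()
    for subject, (_parents, existentials) in tbox.merged_axioms().items():
        if not existentials:
            continue
        subs = tbox.concept_descendants(subject)
        for r, b in existentials:
            role_ups = tbox.role_ancestors(r)
            filler_ups = tbox.ancestors(b)
            for a, ru, bu in itertools.product(subs, role_ups, filler_ups):
                triples.add(RelTriple(a, ru, bu))
    return RelationshipBase(frozenset(triples), provenance="inferred")


def entails_triple(tbox: TBox, triple: RelTriple) -> bool:
    """True iff ``TBox ⊨ subject ⊑ ∃role.object``, without materialising InfRB."""
    tbox._require_concept(triple.subject)
    tbox._require_role(triple.role)
    tbox._require_concept(triple.object)
    subject_ups = tbox.ancestors(triple.subject)
    object_downs = tbox.concept_descendants(triple.object)
    for ax in tbox.axioms:
        if ax.subject not in subject_ups:
            continue
        for r, b in ax.existentials:
            if b in object_downs and role_subsumes(tbox, triple.role, r):
                return True
    return False


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _records(path: Path) -> Iterator[tuple[int, list[str]]]:
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        yield lineno, line.split("\t")


_INCLUSION_MARKERS = {"subclassof", "sub", "⊑", "<="}
_EQUIVALENCE_MARKERS = {"equivalentto", "equiv", "≡", "=="}


def parse_tbox(
    concepts_file: str | Path,
    roles_file: str | Path,
    axioms_file: str | Path,
) -> TBox:
    """Load a TBox from the three-file TSV dialect (see module docstring).

    Raises :class:`TBoxLoadError` naming the file and line on malformed
    records, unresolvable ids or equivalence axioms; :class:`OntologyError`
    on taxonomy/role-hierarchy cycles.
    """
    concepts_file, roles_file, axioms_file = (
        Path(concepts_file),
        Path(roles_file),
        Path(axioms_file),
    )
    concepts: dict[str, Concept] = {}
    for lineno, cols in _records(concepts_file):
        if len(cols) != 3:
            raise TBoxLoadError(
                f"{concepts_file}:{lineno}: expected 3 columns, got {len(cols)}"
            )
        cid, label, stype = (c.strip() for c in cols)
        if cid in concepts:
            raise TBoxLoadError(f"{concepts_file}:{lineno}: duplicate concept id {cid!r}")
        try:
            concepts[cid] = Concept(cid, label, stype)
        except OntologyError as exc:
            raise TBoxLoadError(f"{concepts_file}:{lineno}: {exc}") from exc

    roles: dict[str, Role] = {}
    for lineno, cols in _records(roles_file):
        if len(cols) not in (2, 3):
            raise TBoxLoadError(
                f"{roles_file}:{lineno}: expected 2-3 columns, got {len(cols)}"
            )
        rid, label = cols[0].strip(), cols[1].strip()
        parent = cols[2].strip() if len(cols) == 3 and cols[2].strip() else None
        if rid in roles:
            raise TBoxLoadError(f"{roles_file}:{lineno}: duplicate role id {rid!r}")
        roles[rid] = Role(rid, label, parent)

    axioms: list[Axiom] = []
    for lineno, cols in _records(axioms_file):
        if len(cols) not in (3, 4):
            raise TBoxLoadError(
                f"{axioms_file}:{lineno}: expected 3-4 columns, got {len(cols)}"
            )
        if len(cols) == 4:
            op = cols[3].strip().lower()
            if op in _EQUIVALENCE_MARKERS:
                raise TBoxLoadError(
                    f"{axioms_file}:{lineno}: equivalence axioms are not supported; "
                    "only primitive inclusions (⊑) are admitted"
                )
            if op not in _INCLUSION_MARKERS:
                raise TBoxLoadError(f"{axioms_file}:{lineno}: unknown operator {op!r}")
        subject = cols[0].strip()
        parents = frozenset(p.strip() for p in cols[1].split(",") if p.strip())
        existentials = set()
        for pair in cols[2].split(","):
            pair = pair.strip()
            if not pair:
                continue
            if ":" not in pair:
                raise TBoxLoadError(
                    f"{axioms_file}:{lineno}: malformed existential {pair!r} "
                    "(expected role_id:filler_id)"
                )
            r, b = pair.split(":", 1)
            existentials.add((r.strip(), b.strip()))
        try:
            axioms.append(Axiom(subject, parents, frozenset(existentials)))
        except OntologyError as exc:
            raise TBoxLoadError(f"{axioms_file}:{lineno}: {exc}") from exc

    try:
        return TBox(concepts=concepts, roles=roles, axioms=axioms)
    except OntologyError as exc:
        raise TBoxLoadError(f"{axioms_file}: {exc}") from exc


def write_tbox(tbox: TBox, concepts_file: str | Path, roles_file: str | Path,
               axioms_file: str | Path) -> None:
    """Serialise a TBox back into the three-file TSV dialect."""
    with open(concepts_file, "w", encoding="utf-8") as fh:
        for c in sorted(tbox.concepts.values(), key=lambda c: c.id):
            fh.write(f"{c.id}\t{c.label}\t{c.semantic_type}\n")
    with open(roles_file, "w", encoding="utf-8") as fh:
        for r in sorted(tbox.roles.values(), key=lambda r: r.id):
            fh.write(f"{r.id}\t{r.label}\t{r.parent or ''}\n")
    with open(axioms_file, "w", encoding="utf-8") as fh:
        for ax in tbox.axioms:
            parents = ",".join(sorted(ax.named_parents))
            exts = ",".join(f"{r}:{b}" for r, b in sorted(ax.existentials))
            fh.write(f"{ax.subject}\t{parents}\t{exts}\n")


def read_triples(path: str | Path, provenance: str = "external") -> RelationshipBase:
    """Read a pipe-separated ``A|R|B`` triple file into a RelationshipBase."""
    triples = set()
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        try:
            triples.add(RelTriple.parse(line))
        except OntologyError as exc:
            raise TBoxLoadError(f"{path}:{lineno}: {exc}") from exc
    return RelationshipBase(frozenset(triples), provenance=provenance)


def write_triples(rb: RelationshipBase | Iterable[RelTriple], path: str | Path) -> None:
    triples = rb.triples if isinstance(rb, RelationshipBase) else frozenset(rb)
    with open(path, "w", encoding="utf-8") as fh:
        for t in sorted(triples, key=lambda t: (t.subject, t.role, t.object)):
            fh.write(f"{t}\n")
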