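"""Distant supervision: align annotated sentences with a relationship base.

Given a sentence mentioning concepts ``A`` and ``B`` (in that textual
order) and a relationship base containing ``A|r|B``, the text between the
two mentions is taken as lexical evidence for the relation ``r`` and the
pair becomes a labeled training example.  The same machinery, run with the
label left absent, produces the unlabeled candidate instances the trained
classifier later predicts on.

By default only the subject-before-object textual order is aligned.  A
mention pair related by several roles yields one instance per role
(``drop_ambiguous`` removes such pairs); ``with_none_class`` additionally
emits co-occurring but unrelated pairs under the ``NONE`` label so a
no-relation class can be trained; ``both_orders`` also checks triples whose
subject mention follows its object mention in the text.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from .corpus import AnnotatedSentence, Corpus, Mention
from .ontology import RelationshipBase, RelTriple, TBox

__all__ = [
    "RelationInstance",
    "NONE_LABEL",
    "extract_between_string",
    "align_corpus",
    "candidate_instances",
    "read_instances",
    "write_instances",
]

logger = logging.getLogger(__name__)

NONE_LABEL = "NONE"


@dataclass(frozen=True)
class RelationInstance:
    """An ordered concept-mention pair and its classification payload.

    ``between`` is the lowercased, trimmed sentence fragment between the
    two mentions.  ``order`` is ``forward`` when the subject mention
    precedes the object mention in the text (the default alignment mode)
    and ``reverse`` otherwise.  ``label`` is the role id for training
    instances and ``None`` for prediction candidates.
    """

    sentence_index: int
    subject: str
    object: str
    between: str
    subject_type: str
    object_type: str
    label: str | None = None
    order: str = "forward"


def extract_between_string(
    sentence: AnnotatedSentence, first: Mention, second: Mention
) -> str:
    """Lowercased, trimmed text between two non-overlapping mentions."""
    if first.end > second.start:
        raise ValueError(
            f"mentions overlap or are out of order: [{first.start},{first.end}) "
            f"vs [{second.start},{second.end})"
        )
    return sentence.text[first.end : second.start].strip().lower()


def _pair_roles(rb: RelationshipBase) -> dict[tuple[str, str], list[str]]:
    index: dict[tuple[str, str], list[str]] = {}
    for t in rb:
        index.setdefault((t.subject, t.object), []).append(t.role)
    return {k: sorted(v) for k, v in index.items()}


def align_corpus(
    corpus: Corpus,
    rb: RelationshipBase,
    tbox: TBox,
    *,
    both_orders: bool = False,
    drop_ambiguous: bool = False,
    with_none_class: bool = False,
) -> list[RelationInstance]:
    """Produce labeled relation instances by distant supervision.

    For every ordered mention pair in a sentence and every role relating
    the two concepts in ``rb``, one labeled instance is emitted.  Sentences
    mentioning a concept absent from the TBox are skipped with a warning.
    Output order is deterministic: (sentence index, subject mention start,
    object mention start, role id).
    """
    index = _pair_roles(rb)
    keyed: list[tuple[tuple[int, int, int, str], RelationInstance]] = []
    for si, sentence in enumerate(corpus):
        unknown = [m.concept for m in sentence.mentions if m.concept not in tbox.concepts]
        if unknown:
            logger.warning(
                "sentence %d: unresolvable concept(s) %s; skipped", si, sorted(set(unknown))
            )
            continue
        mentions = sentence.mentions
        for i in range(len(mentions)):
            for j in range(i + 1, len(mentions)):
                m1, m2 = mentions[i], mentions[j]
                if m1.end > m2.start:  # overlapping mentions: no between-string
                    continue
                between = extract_between_string(sentence, m1, m2)
                directed = [(m1, m2, "forward")]
                if both_orders:
                    directed.append((m2, m1, "reverse"))
                for subj_m, obj_m, order in directed:
                    roles = index.get((subj_m.concept, obj_m.concept), [])
                    if drop_ambiguous and len(roles) > 1:
                        continue
                    if not roles and with_none_class and order == "forward":
                        roles = [NONE_LABEL]
                    for role in roles:
                        inst = RelationInstance(
                            sentence_index=si,
                            subject=subj_m.concept,
                            object=obj_m.concept,
                            between=between,
                            subject_type=tbox.semantic_type(subj_m.concept),
                            object_type=tbox.semantic_type(obj_m.concept),
                            label=role,
                            order=order,
                        )
                        keyed.append(((si, subj_m.start, obj_m.start, role), inst))
    keyed.sort(key=lambda kv: kv[0])
    return [inst for _, inst in keyed]


def candidate_instances(corpus: Corpus, tbox: TBox) -> list[RelationInstance]:
    """Unlabeled instances for every forward-ordered mention pair.

    These are the prediction inputs of the definition-generation stage:
    every co-occurring concept pair is a candidate relationship whose role
    the classifier assigns.
    """
    out: list[RelationInstance] = []
    for si, sentence in enumerate(corpus):
        if any(m.concept not in tbox.concepts for m in sentence.mentions):
            logger.warning("sentence %d: unresolvable concept(s); skipped", si)
            continue
        mentions = sentence.mentions
        for i in range(len(mentions)):
            for j in range(i + 1, len(mentions)):
                m1, m2 = mentions[i], mentions[j]
                if m1.end > m2.start:
                    continue
                out.append(
                    RelationInstance(
                        sentence_index=si,
                        subject=m1.concept,
                        object=m2.concept,
                        between=extract_between_string(sentence, m1, m2),
                        subject_type=tbox.semantic_type(m1.concept),
                        object_type=tbox.semantic_type(m2.concept),
                        label=None,
                    )
                )
    return out


_COLUMNS = ("sentence_index", "subject", "object", "subject_type", "object_type",
            "label", "between", "order")


def write_instances(instances: Iterable[RelationInstance], path: str | Path) -> None:
    """Serialise instances as TSV (one header line, one instance per row)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_COLUMNS) + "\n")
        for inst in instances:
            fh.write(
                "\t".join(
                    [
                        str(inst.sentence_index),
                        inst.subject,
                        inst.object,
                        inst.subject_type,
                        inst.object_type,
                        inst.label if inst.label is not None else "",
                        inst.between,
                        inst.order,
                    ]
                )
                + "\n"
            )


def read_instances(path: str | Path) -> list[RelationInstance]:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines:
        return []
    out = []
    for lineno, line in enumerate(lines[1:], 2):
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) != len(_COLUMNS):
            raise ValueError(f"{path}:{lineno}: expected {len(_COLUMNS)} columns")
        out.append(
            RelationInstance(
                sentence_index=int(cols[0]),
                subject=cols[1],
                object=cols[2],
                subject_type=cols[3],
                object_type=cols[4],
                label=cols[5] or None,
                between=cols[6],
                order=cols[7],
            )
        )
    return out
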