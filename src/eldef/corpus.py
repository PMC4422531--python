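"""Concept-annotated sentences: container types, JSON-lines I/O and a
dictionary annotator.

A corpus is a sequence of sentences, each carrying character-span concept
mentions (0-based, half-open).  On disk a corpus is JSON-lines, one object
per sentence::

    {"text": "...", "source": "...",
     "mentions": [{"concept": "...", "start": 0, "end": 9}, ...]}

The dictionary annotator matches concept labels against raw text
(case-insensitive, whitespace-normalised, word-boundary anchored,
longest-match-first, non-overlapping).  It stands in for an external
biomedical annotation service: on synthetic corpora whose sentences are
built from the very same labels it is exact, which is the point — it lets
the downstream alignment and learning stages be exercised without
annotation noise.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

from .ontology import TBox

__all__ = [
    "Mention",
    "AnnotatedSentence",
    "Corpus",
    "CorpusError",
    "read_corpus",
    "write_corpus",
    "annotate_with_dictionary",
]

logger = logging.getLogger(__name__)


class CorpusError(ValueError):
    """Malformed corpus file or invalid mention span."""


@dataclass(frozen=True)
class Mention:
    """A concept mention: ``text[start:end]`` refers to ``concept``."""

    concept: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CorpusError(
                f"mention {self.concept!r}: invalid span [{self.start}, {self.end})"
            )


@dataclass(frozen=True)
class AnnotatedSentence:
    """Raw sentence text plus its concept mentions, sorted by start offset."""

    text: str
    mentions: tuple[Mention, ...] = ()
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "mentions", tuple(sorted(self.mentions, key=lambda m: (m.start, m.end)))
        )
        for m in self.mentions:
            if m.end > len(self.text):
                raise CorpusError(
                    f"mention {m.concept!r} span [{m.start}, {m.end}) exceeds "
                    f"sentence length {len(self.text)}"
                )

    def covered_text(self, mention: Mention) -> str:
        return self.text[mention.start : mention.end]


@dataclass
class Corpus:
    """A sequence of annotated sentences."""

    sentences: list[AnnotatedSentence] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sentences)

    def __iter__(self) -> Iterator[AnnotatedSentence]:
        return iter(self.sentences)


def read_corpus(path: str | Path) -> Corpus:
    """Read a JSON-lines corpus; raises CorpusError naming the bad line."""
    sentences = []
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not raw.strip():
            continue
        try:
            obj = json.loads(raw)
            mentions = tuple(
                Mention(m["concept"], int(m["start"]), int(m["end"]))
                for m in obj.get("mentions", [])
            )
            sentences.append(
                AnnotatedSentence(obj["text"], mentions, obj.get("source", ""))
            )
        except (json.JSONDecodeError, KeyError, TypeError) as exc:
            raise CorpusError(f"{path}:{lineno}: malformed sentence record: {exc}") from exc
    return Corpus(sentences)


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write JSON-lines; ``read_corpus(write_corpus(c))`` reproduces ``c``."""
    with open(path, "w", encoding="utf-8") as fh:
        for s in corpus:
            obj = {
                "text": s.text,
                "source": s.source,
                "mentions": [
                    {"concept": m.concept, "start": m.start, "end": m.end}
                    for m in s.mentions
                ],
            }
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


def _label_pattern(label: str) -> re.Pattern[str]:
    # runs of whitespace in the label match runs of whitespace in the text;
    # (?<!\w)/(?!\w) anchor the match at word boundaries
    tokens = label.split()
    body = r"\s+".join(re.escape(tok) for tok in tokens)
    return re.compile(rf"(?<!\w){body}(?!\w)", re.IGNORECASE)


def annotate_with_dictionary(
    text: str, tbox: TBox, source: str = "dictionary"
) -> AnnotatedSentence:
    """Annotate ``text`` with mentions of the TBox's concept labels.

    Matching is case-insensitive, whitespace-normalised and anchored at word
    boundaries.  Candidate matches are selected longest-first; ties are
    broken by leftmost start, then by lexicographic concept id (so when two
    concepts share a label the lexicographically first id wins, which is
    logged).  Selected mentions never overlap.
    """
    candidates: list[tuple[int, int, str]] = []  # (start, end, concept id)
    by_label_span: dict[tuple[int, int], list[str]] = {}
    for concept in tbox.concepts.values():
        if not concept.label.strip():
            continue
        for m in _label_pattern(concept.label).finditer(text):
            candidates.append((m.start(), m.end(), concept.id))
            by_label_span.setdefault((m.start(), m.end()), []).append(concept.id)

    for (start, end), ids in by_label_span.items():
        if len(ids) > 1:
            logger.warning(
                "ambiguous label %r at [%d, %d): candidates %s; keeping %s",
                text[start:end], start, end, sorted(ids), min(ids),
            )

    chosen: list[tuple[int, int, str]] = []
    for start, end, cid in sorted(candidates, key=lambda c: (-(c[1] - c[0]), c[0], c[2])):
        if any(start < e and s < end for s, e, _ in chosen):
            continue
        chosen.append((start, end, cid))

    mentions = tuple(Mention(cid, s, e) for s, e, cid in sorted(chosen))
    return AnnotatedSentence(text, mentions, source=source)


def annotate_corpus(texts: Sequence[str], tbox: TBox, source: str = "dictionary") -> Corpus:
    """Annotate a batch of raw sentences with the dictionary annotator."""
    return Corpus([annotate_with_dictionary(t, tbox, source=source) for t in texts])
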