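"""Featurization of relation instances.

Two feature families are supported, both boolean (presence/absence):

* **Lexical** features of the between-string — bag-of-words, word n-grams
  or character n-grams.  Character trigrams of the fragment between two
  concept mentions capture stems, morphemes and short function words
  ("caused by", "due to") that signal how a relation is verbalised.
* **Semantic-type** features — the semantic types of the two argument
  concepts (``ltype:``/``rtype:``), which encode a relation's domain and
  range constraints.  Alternative type systems (coarser groupings,
  top-level ontology classes) are plugged in as a
  :class:`TypeAssignment` override or a grouping map.

Feature names are namespaced (``bow:``, ``w2:``, ``c3:``, ``ltype:``,
``rtype:``) so lexical and semantic features can never collide.  Vectors
are exported as sparse Weka-dialect ARFF with a nominal class attribute.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse

from .alignment import RelationInstance
from .ontology import TBox

__all__ = [
    "FeatureSpec",
    "TypeAssignment",
    "FeaturizationError",
    "bow",
    "word_ngrams",
    "char_ngrams",
    "lexical_features",
    "semantic_type_features",
    "vectorize_instances",
    "to_sparse_matrix",
    "write_arff",
    "write_vocabulary",
    "read_vocabulary",
]

_PUNCT = ".,;:!?()[]{}\"'`«»—–-/\\"

LEXICAL_MODES = ("bow", "word_ngram", "char_ngram", "none")
NGRAM_SCOPES = ("exact", "up_to")


class FeaturizationError(ValueError):
    """An instance could not be featurized (e.g. concept missing a type)."""


@dataclass(frozen=True)
class FeatureSpec:
    """Which features to extract.

    ``ngram_scope='exact'`` keeps only length-``n`` grams (the default,
    matching presence-set examples built from single-length grams);
    ``'up_to'`` keeps lengths ``1..n``.  ``n`` is ignored for ``bow``.
    ``type_grouping`` optionally collapses semantic types into coarser
    groups before they are emitted as features.
    """

    lexical_mode: str = "char_ngram"
    n: int = 3
    ngram_scope: str = "exact"
    use_types: bool = True
    type_grouping: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if self.lexical_mode not in LEXICAL_MODES:
            raise ValueError(f"lexical_mode must be one of {LEXICAL_MODES}")
        if self.ngram_scope not in NGRAM_SCOPES:
            raise ValueError(f"ngram_scope must be one of {NGRAM_SCOPES}")
        if self.n < 1:
            raise ValueError("n-gram length n must be >= 1")


@dataclass(frozen=True)
class TypeAssignment:
    """Concept-id -> semantic-type map; pluggable type system.

    Defaults come from the TBox (one type per concept); an override file
    or dict emulates alternative type systems, e.g. a foreign semantic
    network or the top-level classes of a taxonomy.
    """

    mapping: Mapping[str, str]

    @classmethod
    def from_tbox(cls, tbox: TBox) -> "TypeAssignment":
        return cls({cid: c.semantic_type for cid, c in tbox.concepts.items()})

    @classmethod
    def from_file(cls, path: str | Path) -> "TypeAssignment":
        mapping = {}
        for raw in Path(path).read_text(encoding="utf-8").splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cid, stype = line.split("\t")
            mapping[cid] = stype
        return cls(mapping)

    def type_of(self, concept: str) -> str:
        try:
            return self.mapping[concept]
        except KeyError:
            raise FeaturizationError(
                f"concept {concept!r} has no semantic type in the type assignment"
            ) from None


# ---------------------------------------------------------------------------
# Lexical features
# ---------------------------------------------------------------------------


def _normalize(s: str) -> str:
    return " ".join(s.lower().split())


def tokenize(s: str) -> list[str]:
    """Lowercase, split on whitespace, strip punctuation from token edges."""
    tokens = [tok.strip(_PUNCT) for tok in s.lower().split()]
    return [t for t in tokens if t]


def bow(between: str) -> frozenset[str]:
    """Unordered set of words of the between-string."""
    return frozenset(tokenize(between))


def word_ngrams(between: str, n: int, scope: str = "exact") -> frozenset[str]:
    """Contiguous word n-grams (space-joined); ``up_to`` includes 1..n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    tokens = tokenize(between)
    lengths = range(1, n + 1) if scope == "up_to" else (n,)
    grams = set()
    for k in lengths:
        grams.update(
            " ".join(tokens[i : i + k]) for i in range(len(tokens) - k + 1)
        )
    return frozenset(grams)


def char_ngrams(between: str, n: int, scope: str = "exact") -> frozenset[str]:
    """Sliding character windows over the normalised string, spaces included.

    No boundary padding is applied; a string shorter than ``n`` yields no
    ``n``-windows.  Duplicate windows collapse (presence semantics).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    s = _normalize(between)
    lengths = range(1, n + 1) if scope == "up_to" else (n,)
    grams = set()
    for k in lengths:
        grams.update(s[i : i + k] for i in range(len(s) - k + 1))
    return frozenset(grams)


def lexical_features(between: str, spec: FeatureSpec) -> frozenset[str]:
    """Namespaced lexical feature names for a between-string."""
    if spec.lexical_mode == "none":
        return frozenset()
    if spec.lexical_mode == "bow":
        return frozenset(f"bow:{t}" for t in bow(between))
    if spec.lexical_mode == "word_ngram":
        return frozenset(
            f"w{len(g.split(' '))}:{g}"
            for g in word_ngrams(between, spec.n, spec.ngram_scope)
        )
    return frozenset(
        f"c{len(g)}:{g}" for g in char_ngrams(between, spec.n, spec.ngram_scope)
    )


# ---------------------------------------------------------------------------
# Semantic features
# ---------------------------------------------------------------------------


def semantic_type_features(
    instance: RelationInstance,
    ta: TypeAssignment,
    grouping: Mapping[str, str] | None = None,
) -> frozenset[str]:
    """The two domain/range features: ``ltype:<subject>``, ``rtype:<object>``."""
    ltype = ta.type_of(instance.subject)
    rtype = ta.type_of(instance.object)
    if grouping:
        ltype = grouping.get(ltype, ltype)
        rtype = grouping.get(rtype, rtype)
    return frozenset({f"ltype:{ltype}", f"rtype:{rtype}"})


# ---------------------------------------------------------------------------
# Vectorization and export
# ---------------------------------------------------------------------------


def featurize_instance(
    instance: RelationInstance, spec: FeatureSpec, ta: TypeAssignment | None
) -> frozenset[str]:
    features = lexical_features(instance.between, spec)
    if spec.use_types:
        if ta is None:
            raise FeaturizationError("use_types=True requires a TypeAssignment")
        features |= semantic_type_features(instance, ta, spec.type_grouping)
    return features


def vectorize_instances(
    instances: Sequence[RelationInstance],
    spec: FeatureSpec,
    ta: TypeAssignment | None = None,
) -> tuple[list[frozenset[str]], list[str]]:
    """Featurize instances; return (presence sets, sorted vocabulary)."""
    vectors = [featurize_instance(inst, spec, ta) for inst in instances]
    vocabulary = sorted(set().union(*vectors)) if vectors else []
    return vectors, vocabulary


def to_sparse_matrix(
    vectors: Sequence[frozenset[str]], vocabulary: Sequence[str]
) -> sparse.csr_matrix:
    """Binary instance x feature matrix; features outside vocabulary ignored."""
    index = {name: j for j, name in enumerate(vocabulary)}
    rows, cols = [], []
    for i, vec in enumerate(vectors):
        for name in vec:
            j = index.get(name)
            if j is not None:
                rows.append(i)
                cols.append(j)
    data = np.ones(len(rows), dtype=np.int8)
    return sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(vectors), len(vocabulary))
    )


def _arff_quote(name: str) -> str:
    if name == "" or any(ch in name for ch in " \t,{}%'\"\\"):
        escaped = name.replace("\\", "\\\\").replace("'", "\\'")
        return f"'{escaped}'"
    return name


def write_arff(
    vectors: Sequence[frozenset[str]],
    vocabulary: Sequence[str],
    labels: Sequence[str],
    path: str | Path,
    relation_name: str = "relation_instances",
) -> None:
    """Write sparse Weka-dialect ARFF: binary numeric attributes + nominal class.

    Output is byte-deterministic for fixed inputs: attribute order follows
    the given vocabulary, class values are sorted, data rows list indices
    in increasing order, and the class value is always written explicitly.
    """
    if len(vectors) != len(labels):
        raise ValueError("vectors and labels must have equal length")
    index = {name: j for j, name in enumerate(vocabulary)}
    classes = sorted(set(labels))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"@relation {_arff_quote(relation_name)}\n\n")
        for name in vocabulary:
            fh.write(f"@attribute {_arff_quote(name)} numeric\n")
        fh.write(
            "@attribute class {" + ",".join(_arff_quote(c) for c in classes) + "}\n"
        )
        fh.write("\n@data\n")
        class_idx = len(vocabulary)
        for vec, label in zip(vectors, labels):
            cols = sorted(index[name] for name in vec if name in index)
            cells = [f"{j} 1" for j in cols]
            cells.append(f"{class_idx} {_arff_quote(label)}")
            fh.write("{" + ", ".join(cells) + "}\n")


def write_vocabulary(vocabulary: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(vocabulary) + ("\n" if vocabulary else ""),
                          encoding="utf-8")


def read_vocabulary(path: str | Path) -> list[str]:
    return [l for l in Path(path).read_text(encoding="utf-8").splitlines() if l]
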