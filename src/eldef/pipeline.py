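"""End-to-end pipeline: annotate -> align -> featurize -> evaluate -> define.

``run_pipeline`` chains the library stages over files on disk, writes every
intermediate artifact into the output directory and emits a machine-readable
run manifest (seed, package version, SHA-256 of every written file) so a
rerun from the same inputs is byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .alignment import align_corpus, candidate_instances, write_instances
from .corpus import Corpus, read_corpus
from .definitions import (
    DefPreReport,
    assemble_definition,
    defpre,
    write_definitions,
)
from .features import (
    FeatureSpec,
    TypeAssignment,
    vectorize_instances,
    write_arff,
    write_vocabulary,
)
from .learning import CVReport, LearnerConfig, cross_validate, predict, train
from .ontology import (
    RelTriple,
    TBox,
    explicit_relationship_base,
    inferred_relationship_base,
    parse_tbox,
    read_triples,
    write_triples,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "run_pipeline_in_memory"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """File locations and stage settings for a full pipeline run."""

    concepts_file: Path
    roles_file: Path
    axioms_file: Path
    corpus_file: Path
    output_dir: Path
    relationship_base: str = "inferred"  # explicit | inferred | <triple file path>
    feature_spec: FeatureSpec = field(default_factory=FeatureSpec)
    learner: LearnerConfig = field(default_factory=LearnerConfig)
    folds: int = 10
    both_orders: bool = False
    drop_ambiguous: bool = False
    with_none_class: bool = False

    def validate(self) -> None:
        for name in ("concepts_file", "roles_file", "axioms_file", "corpus_file"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise PipelineError(f"config: missing input {name}: {p}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> tuple[CVReport, DefPreReport]:
    """Run the full chain on files; returns (CV report, DefPre report).

    Stages: load TBox -> build/load relationship base -> align corpus
    (distant supervision) -> featurize -> 10-fold CV -> train on all
    instances -> predict roles for every co-occurring pair -> assemble
    per-concept definitions -> score them against the input TBox as the
    reference.  All artifacts land in ``config.output_dir``.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def stage(name: str):
        logger.info("pipeline stage: %s", name)

    try:
        stage("load")
        tbox = parse_tbox(config.concepts_file, config.roles_file, config.axioms_file)
        corpus = read_corpus(config.corpus_file)
    except Exception as exc:
        raise PipelineError(f"stage 'load' failed: {exc}") from exc

    try:
        stage("relationship-base")
        if config.relationship_base == "explicit":
            rb = explicit_relationship_base(tbox)
        elif config.relationship_base == "inferred":
            rb = inferred_relationship_base(tbox)
        else:
            rb = read_triples(config.relationship_base)
        write_triples(rb, out / "relationship_base.txt")
        written.append(out / "relationship_base.txt")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'relationship-base' failed: {exc}") from exc

    try:
        stage("align")
        instances = align_corpus(
            corpus, rb, tbox,
            both_orders=config.both_orders,
            drop_ambiguous=config.drop_ambiguous,
            with_none_class=config.with_none_class,
        )
        logger.info("aligned %d labeled instances from %d sentences (%s base, %d triples)",
                    len(instances), len(corpus), rb.provenance, len(rb))
        write_instances(instances, out / "instances.tsv")
        written.append(out / "instances.tsv")
    except Exception as exc:
        raise PipelineError(f"stage 'align' failed: {exc}") from exc

    try:
        stage("featurize")
        ta = TypeAssignment.from_tbox(tbox)
        vectors, vocabulary = vectorize_instances(instances, config.feature_spec, ta)
        labels = [i.label for i in instances]
        write_arff(vectors, vocabulary, labels, out / "instances.arff")
        write_vocabulary(vocabulary, out / "vocabulary.txt")
        written += [out / "instances.arff", out / "vocabulary.txt"]
    except Exception as exc:
        raise PipelineError(f"stage 'featurize' failed: {exc}") from exc

    try:
        stage("cross-validate")
        cv_report = cross_validate(vectors, labels, config.learner, folds=config.folds)
        (out / "cv_report.json").write_text(cv_report.to_json() + "\n", encoding="utf-8")
        written.append(out / "cv_report.json")
    except Exception as exc:
        raise PipelineError(f"stage 'cross-validate' failed: {exc}") from exc

    try:
        stage("train-predict-define")
        model = train(vectors, labels, config.learner, vocabulary)
        cands = candidate_instances(corpus, tbox)
        cand_vectors, _ = vectorize_instances(cands, config.feature_spec, ta)
        predicted = predict(model, cand_vectors)
        by_subject: dict[str, set[RelTriple]] = {}
        for inst, role in zip(cands, predicted):
            by_subject.setdefault(inst.subject, set()).add(
                RelTriple(inst.subject, role, inst.object)
            )
        definitions = [
            assemble_definition(subject, triples)
            for subject, triples in sorted(by_subject.items())
        ]
        write_definitions(
            definitions,
            axioms_path=out / "definitions.tsv",
            text_path=out / "definitions.txt",
        )
        written += [out / "definitions.tsv", out / "definitions.txt"]
    except Exception as exc:
        raise PipelineError(f"stage 'train-predict-define' failed: {exc}") from exc

    try:
        stage("defpre")
        defpre_report = defpre(
            {s: sorted(t, key=str) for s, t in sorted(by_subject.items())}, tbox
        )
        (out / "defpre_report.json").write_text(
            defpre_report.to_json() + "\n", encoding="utf-8"
        )
        written.append(out / "defpre_report.json")
    except Exception as exc:
        raise PipelineError(f"stage 'defpre' failed: {exc}") from exc

    manifest = {
        "package_version": __version__,
        "seed": config.learner.seed,
        "relationship_base": config.relationship_base,
        "feature_spec": {
            "lexical_mode": config.feature_spec.lexical_mode,
            "n": config.feature_spec.n,
            "ngram_scope": config.feature_spec.ngram_scope,
            "use_types": config.feature_spec.use_types,
        },
        "learner": {
            "algorithm": config.learner.algorithm,
            "complexity": config.learner.complexity,
            "epsilon": config.learner.epsilon,
            "seed": config.learner.seed,
        },
        "counts": {
            "sentences": len(corpus),
            "relationship_base_triples": len(rb),
            "labeled_instances": len(instances),
            "candidate_pairs": len(cands),
            "defined_concepts": len(by_subject),
        },
        "artifacts": {p.name: _sha256(p) for p in sorted(written)},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return cv_report, defpre_report


def run_pipeline_in_memory(
    tbox: TBox,
    corpus: Corpus,
    *,
    relationship_base: str = "inferred",
    feature_spec: FeatureSpec | None = None,
    learner: LearnerConfig | None = None,
    folds: int = 10,
) -> tuple[CVReport, DefPreReport]:
    """The same chain without touching disk (convenience for experiments)."""
    feature_spec = feature_spec or FeatureSpec()
    learner = learner or LearnerConfig()
    rb = (
        explicit_relationship_base(tbox)
        if relationship_base == "explicit"
        else inferred_relationship_base(tbox)
    )
    instances = align_corpus(corpus, rb, tbox)
    ta = TypeAssignment.from_tbox(tbox)
    vectors, vocabulary = vectorize_instances(instances, feature_spec, ta)
    labels = [i.label for i in instances]
    cv_report = cross_validate(vectors, labels, learner, folds=folds)
    model = train(vectors, labels, learner, vocabulary)
    cands = candidate_instances(corpus, tbox)
    cand_vectors, _ = vectorize_instances(cands, feature_spec, ta)
    predicted = predict(model, cand_vectors)
    by_subject: dict[str, set[RelTriple]] = {}
    for inst, role in zip(cands, predicted):
        by_subject.setdefault(inst.subject, set()).add(
            RelTriple(inst.subject, role, inst.object)
        )
    defpre_report = defpre(by_subject, tbox)
    return cv_report, defpre_report
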