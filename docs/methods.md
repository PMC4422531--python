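# Methods

## The task

Most biomedical vocabularies define concepts only as free text, while a
formally defined terminology such as SNOMED CT states, in the description
logic EL, what a concept *is*: `Baritosis ⊑ Pneumoconiosis ⊓
∃Causative_agent.Barium_dust`.  `eldef` implements a supervised pipeline
that turns textual definitions into such flat EL inclusion axioms:

1. **Annotation** — concept mentions are located in each sentence (a
   dictionary matcher over concept labels; pre-annotated corpora are also
   accepted).
2. **Distant supervision** — a sentence mentioning concepts `A` and `B`
   (in that order) is aligned with every relation `r` for which `A|r|B`
   is in a relationship base; the text *between* the two mentions becomes
   a labeled training example for `r`.
3. **Featurization** — boolean lexical features of the between-string
   (bag-of-words, word n-grams or character n-grams) plus two semantic
   features, the types of the subject and object concepts, which encode
   the relation's domain and range constraints.
4. **Classification** — a multi-class linear SVM (C = 1.0) assigns a
   relation to each co-occurring concept pair; evaluated by macro-averaged
   F1 under stratified 10-fold cross-validation.
5. **Definition assembly** — predicted triples sharing a subject are
   folded into one axiom `A ⊑ ⊓_i ∃R_i.B_i` (triples of a designated is-a
   role become named parents).
6. **Evaluation by entailment** — the *definition precision* of a set of
   candidate triples is the fraction the reference terminology entails:
   `DefPre = |{A|R|B ∈ Cands : T ⊨ A ⊑ ∃R.B}| / |Cands|`.

## The reasoning fragment

The reasoner covers exactly the fragment flat primitive definitions live
in: inclusions whose right side is a conjunction of concept names and
existential restrictions with *named* fillers, plus an optional role
hierarchy.  No role chains, nominals, bottom, concrete domains or general
concept inclusions.  In this fragment:

* subsumption between names is the reflexive–transitive closure of the
  named-parent edges (multiple axioms per subject merge their conjuncts);
* `T ⊨ A ⊑ ∃R.B` iff some axiom subject `A'` with existential `(R', B')`
  satisfies `A ⊑ A'`, `R' ⊑ R` (role hierarchy) and `B' ⊑ B`.

This closure rule is complete for the fragment because nothing else in
the syntax can produce an existential consequence.  Completeness is not
assumed: the test suite checks exact set equality between the closure
reasoner and a brute-force oracle (depth-first path enumeration over raw
parent edges, no shared code) on 200 random terminologies, and that the
explicit base is always a subset of the inferred one (monotonicity).

A real clinical terminology is computed under richer EL++ semantics
(role groups, some role chains); relationships contributed by those
constructs are outside this fragment, a known gap.

Only inclusion axioms are accepted; an equivalence axiom in an input file
is a load error, because the pipeline deliberately generates primitive
(necessary-condition) definitions only.

## The synthetic benchmark

Real corpora for this task (clinical terminologies, curated thesauri,
their aligned sentence collections) are licensed, so the package ships a
generator that reproduces the *statistical structure* the method exploits,
with every quantity a pure function of the seed:

* a taxonomy tree grown breadth-first with Poisson(`taxonomy_branching`)
  children per node; every concept gets one of `n_types` semantic types
  (round-robin over a shuffled order, so all types are populated);
* each role receives a (domain-type, range-type) signature;
  `type_overlap` θ collapses signature diversity — the number of distinct
  signatures is `max(1, round(n_roles − θ·(n_roles − 1)))`, so θ=0 gives
  all-distinct signatures and θ=1 one signature shared by all roles (for
  intermediate θ the realised fraction of sharing role pairs is
  approximate, which is sufficient for the monotonicity claims made);
* `triples_per_role` ground-truth relationships per role connect
  type-compatible concept pairs as flat existential axioms;
* each triple is verbalised as `sentences_per_triple` sentences
  `<subject label> <template> <object label>` with exact gold mentions;
  each role owns `patterns_per_role` short English-like templates, and
  with probability `pattern_noise` a sentence borrows a template from a
  different role.  Noise is injected into the lexical channel only —
  type assignments are always correct, matching the setting where types
  come from curated resources.

Defaults: 60 concepts, branching 3, 3 roles (the three dominant disorder
relations of a clinical terminology motivate this count), 6 types,
θ = 0, 4 templates/role, noise 0.1, 2 sentences/triple, 20 triples/role —
about 120 sentences and 40 instances per class, enough for stable 10-fold
CV while keeping the default test run in seconds.

What the generator does **not** emulate: real annotation noise (labels are
exact, so the dictionary annotator is perfect on synthetic text), natural
sentence variety beyond the template pool, mention-distance effects and
multi-sentence discourse.  Passing tests therefore demonstrate the
pipeline's mechanics and its qualitative behaviour (type signatures
dominate when disjoint; reasoning enlarges the training set), not
performance on clinical text.

## Features and learning

* Between-strings are lowercased and trimmed at extraction.  Tokenisation
  for word features: whitespace split, punctuation stripped from token
  edges.  Character n-grams slide over the whitespace-normalised string,
  spaces included, with no boundary padding.
* All features are boolean presence indicators, namespaced (`bow:`,
  `w2:`, `c3:`, `ltype:`, `rtype:`) so families cannot collide.  Weighted
  variants, feature selection, and the combination of word and character
  n-grams are deliberately out of scope.
* `ngram_scope` defaults to `exact` (only length-n grams), with `up_to`
  (lengths 1..n) available — the worked example this package reproduces
  lists single-length gram sets, which is the testable anchor.
* The default classifier is `SVC(kernel="linear", C=1.0)`; libsvm's
  pairwise multiclass scheme is used as provided.  Logistic regression,
  multinomial naive Bayes and random forests sit behind the same
  interface; the linear SVM is the reference setting.
* Cross-validation: `StratifiedKFold(shuffle=True, random_state=seed)`;
  per-class precision/recall/F1 are recomputed from the pooled confusion
  matrix; macro-F is the unweighted mean of per-class F1; a class with
  zero predicted and zero true positives gets F1 = 0.  If the rarest
  class has fewer instances than the requested folds, the fold count is
  reduced with a warning.

## Definition scoring conventions

* `DefPre` is computed over triples, exactly as defined above; a
  per-definition all-triples-entailed flag is additionally reported.
* Per-concept aggregation: the macro precision averages over concepts
  with at least one candidate, *including* those whose candidates are all
  wrong (zero-precision concepts); a second figure excluding them is also
  reported, since both aggregations are in common use.  Concepts are
  unweighted by candidate count.
* Candidates with unresolvable ids score as not entailed (with a
  warning) — the desired behaviour for out-of-vocabulary predictions.
* The optional simplifier prunes a named parent that subsumes another
  named parent, and an existential `(R, B)` when `(R, B')` with `B' ⊑ B`
  is present; it is idempotent and never changes the entailed
  consequences of the definition.

## Determinism

Every random draw (benchmark generation, fold shuffling, estimator
seeds) descends from explicit integer seeds; ARFF exports, CV reports and
DefPre reports are byte-identical across reruns with the same seed, and
the pipeline writes a manifest (seed, version, SHA-256 of every artifact)
to make this checkable.

## Known limitations

* The reasoner is complete only for the flat fragment (see above).
* The dictionary annotator does no disambiguation beyond
  lexicographic-id tie-breaking and no abbreviation handling; it is a
  stand-in for a full biomedical annotation service.
* Only same-sentence, surface-order mention pairs are aligned by default
  (`--both-orders` relaxes order); no distance cap is applied.
* Tokenisation rules are fixed and documented but necessarily differ in
  detail from any particular legacy preprocessing toolchain.
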