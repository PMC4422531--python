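"""How much signal do semantic types carry?  A controlled experiment.

The synthetic benchmark lets the overlap of the relations' (domain, range)
type signatures be dialled: at overlap 0 each relation has its own
signature and the two type features alone identify it; at overlap 1 all
relations share one signature and only the lexical between-string can
discriminate.  Cross-validated macro-F (the unweighted mean of per-class
F1) makes the trade-off visible.
"""

from eldef import (
    FeatureSpec, LearnerConfig, SimConfig, TypeAssignment,
    align_corpus, cross_validate, simulate_benchmark, vectorize_instances,
)


def macro_f(theta: float, noise: float, lexical: str) -> float:
    tbox, corpus, _gold, exp_rb, _inf = simulate_benchmark(
        SimConfig(seed=31, type_overlap=theta, pattern_noise=noise)
    )
    instances = align_corpus(corpus, exp_rb, tbox)
    vectors, _ = vectorize_instances(
        instances,
        FeatureSpec(lexical_mode=lexical, use_types=True),
        TypeAssignment.from_tbox(tbox),
    )
    report = cross_validate(
        vectors, [i.label for i in instances], LearnerConfig(seed=31)
    )
    return report.macro_f


print("type features only, signature overlap 0.0:",
      f"macro-F = {macro_f(0.0, 0.1, 'none'):.3f}")
print("type features only, signature overlap 1.0:",
      f"macro-F = {macro_f(1.0, 0.0, 'none'):.3f}")
print("char 3-grams + types, signature overlap 1.0:",
      f"macro-F = {macro_f(1.0, 0.0, 'char_ngram'):.3f}")
# Disjoint domain/range signatures make the task near-trivial for the
# classifier; once signatures fully overlap, types drop to chance level
# and the lexical channel carries the remaining signal.
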