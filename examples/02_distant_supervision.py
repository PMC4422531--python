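"""From a raw definitional sentence to a labeled training instance.

The dictionary annotator finds concept mentions; distant supervision
aligns the mention pair with the relationship base, labelling the text
between the mentions with the relation that links the two concepts.  The
between-string then yields the lexical features (bag-of-words, word
bigrams, character trigrams) and the concept types the semantic features.
"""

from eldef import (
    Axiom, Concept, Corpus, Role, TBox,
    align_corpus, annotate_with_dictionary, bow, char_ngrams,
    explicit_relationship_base, word_ngrams,
)

tbox = TBox(
    concepts={
        "Baritosis": Concept("Baritosis", "Baritosis", "disorder"),
        "Pneumoconiosis": Concept("Pneumoconiosis", "Pneumoconiosis", "disorder"),
        "Barium_dust": Concept("Barium_dust", "barium dust", "substance"),
        "Dust": Concept("Dust", "dust", "substance"),
    },
    roles={"Causative_agent": Role("Causative_agent", "causative agent")},
    axioms=[
        Axiom("Baritosis", frozenset({"Pneumoconiosis"}),
              frozenset({("Causative_agent", "Barium_dust")})),
        Axiom("Barium_dust", frozenset({"Dust"}), frozenset()),
    ],
)

sentence = annotate_with_dictionary(
    "Baritosis is pneumoconiosis caused by barium dust", tbox
)
for m in sentence.mentions:
    print(f"mention: {sentence.text[m.start:m.end]!r} -> {m.concept} [{m.start},{m.end})")

instances = align_corpus(Corpus([sentence]), explicit_relationship_base(tbox), tbox)
inst = instances[0]
print("label:        ", inst.label)
print("between:      ", repr(inst.between))
print("type pair:    ", (inst.subject_type, inst.object_type))
print("BoW:          ", sorted(bow(inst.between)))
print("word 2-grams: ", sorted(word_ngrams(inst.between, 2)))
trigrams = char_ngrams(inst.between, 3)
print(f"char 3-grams:  {len(trigrams)} unique (25 windows, one duplicate)")
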