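"""Feature descriptors from a mutation-profiled tuple.

Builds a 23-sequence dataset carrying the tuple <GGAGAUG, UGGAGACU> 16 times
verbatim and 7 times as the variant [SUB 0 5 U C, DEL 1 6 C] (a U->C
substitution in the first motif plus a deleted C in the second), runs the
full discovery pipeline, and encodes three query sequences.  An exact match
scores 1.0; the recognized variant scores 7/16 = 0.4375 (its record frequency
over the tuple's exact frequency); an unrelated sequence scores 0.
"""

from seqtuples import (
    RNA,
    GeneratorConfig,
    MinerConfig,
    PlantedTupleSpec,
    SequenceRecord,
    encode_sequence,
    feature_pipeline,
    generate_synthetic,
    write_libsvm,
)

spec = PlantedTupleSpec(
    members=("GGAGAUG", "UGGAGACU"),
    gap_range=(3, 12),
    exact_fraction=16 / 23,
    variants=(("SUB 0 5 U C DEL 1 6 C", 7 / 23),),
)
dataset, _ = generate_synthetic(
    GeneratorConfig(n_sequences=23, sequence_length=60, alphabet=RNA,
                    planted=(spec,), seed=11)
)

profiles = feature_pipeline(dataset, MinerConfig(min_support=10, min_len=7, max_len=8))
target = [p for p in profiles if p.tuple.members == ("GGAGAUG", "UGGAGACU")]
prof = target[0]
print(f"profiled tuple: <{', '.join(prof.tuple.members)}>")
print(f"  exact placements: {prof.exact_frequency}")
for record, freq in prof.entries:
    print(f"  variant [{record}]: {freq}")

queries = [
    SequenceRecord("exact", "GGAGGAGAUGGGGUCCUGGAGACUAAG"),
    SequenceRecord("variant", "GGAGGAGACGGGUCCUGGAGAUAAG"),
    SequenceRecord("unrelated", "ACACACACACACACAC"),
]
for q in queries:
    component = encode_sequence(q, target)[0]
    print(f"component for {q.id!r}: {component}")

# the same vectors, written as a labeled sparse libsvm training file
import tempfile

vectors = [encode_sequence(q, target) for q in queries]
with tempfile.NamedTemporaryFile("r+", suffix=".libsvm") as tmp:
    write_libsvm(vectors, [1, 1, -1], tmp.name)
    print("libsvm lines:")
    print(tmp.read(), end="")
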