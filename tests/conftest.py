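import pytest

from seqtuples import (
    RNA,
    GeneratorConfig,
    MinerConfig,
    PlantedTupleSpec,
    SequenceRecord,
    build_profiles,
    discover_tuples,
    generate_synthetic,
)

WORKED_MEMBERS = ("GGAGAUG", "UGGAGACU")
WORKED_RECORD = "SUB 0 5 U C DEL 1 6 C"
EXACT_MATCH_SEQ = "GGAGGAGAUGGGGUCCUGGAGACUAAG"
APPROX_MATCH_SEQ = "GGAGGAGACGGGUCCUGGAGAUAAG"  # the '_' deletion removed


def records(*residues, prefix="s"):
    return [SequenceRecord(f"{prefix}{i + 1}", r) for i, r in enumerate(residues)]


@pytest.fixture(scope="session")
def worked_example_dataset():
    """23 RNA sequences: 16 exact plantings of the two-motif tuple and 7
    plantings of its SUB+DEL variant."""
    spec = PlantedTupleSpec(
        members=WORKED_MEMBERS,
        gap_range=(3, 12),
        exact_fraction=16 / 23,
        variants=((WORKED_RECORD, 7 / 23),),
    )
    cfg = GeneratorConfig(
        n_sequences=23, sequence_length=60, alphabet=RNA, planted=(spec,), seed=20210
    )
    return generate_synthetic(cfg)


@pytest.fixture(scope="session")
def worked_example_profiles(worked_example_dataset):
    """Full pipeline output (mine -> combinations -> tuples -> profiles)."""
    dataset, _ = worked_example_dataset
    cfg = MinerConfig(min_support=10, min_len=7, max_len=8)
    tuples = discover_tuples(dataset, cfg)
    return build_profiles(tuples, dataset)


@pytest.fixture(scope="session")
def worked_example_profile(worked_example_profiles):
    """The profile of the planted two-member tuple alone."""
    target = [p for p in worked_example_profiles if p.tuple.members == WORKED_MEMBERS]
    assert len(target) == 1
    return target[0]
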