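from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import closed_multisets, multiset_placements, powerset_closed_itemsets

from seqtuples import (
    RNA,
    ConfigurationError,
    FrequentSubsequence,
    GeneratorConfig,
    MinerConfig,
    PlantedTupleSpec,
    SymbolCombination,
    build_occurrence_table,
    count_ordered_placements,
    derive_ordered_tuples,
    discover_tuples,
    expand_duplicates,
    generate_synthetic,
    mine_closed_combinations,
)
from conftest import records


def fs(residues, ids):
    return FrequentSubsequence(residues, frozenset(ids), 0)


class TestOccurrenceTable:
    def test_nonoverlapping_leftmost_greedy_cell(self):
        ds = records("ACGACGACG")
        table = build_occurrence_table(ds, [fs("ACGACG", {"s1"})])
        assert table.cell("s1", "ACGACG") == 1

    def test_absent_column_gives_zero_row(self):
        ds = records("TTTT")
        table = build_occurrence_table(ds, [fs("ACG", set())])
        assert table.cell("s1", "ACG") == 0
        assert table.counts["s1"] == {}

    def test_two_sequences_each_with_both_symbols(self):
        # two sequences, each containing alpha once and beta once
        ds = records("GGAGGAGAUGGGGCCUGGAGACUAAG", "GGAGGAGAUGGGGCCUGGAGACUAAG")
        table = build_occurrence_table(
            ds, [fs("GGAGAUG", {"s1", "s2"}), fs("UGGAGACU", {"s1", "s2"})]
        )
        assert table.to_dataframe().values.tolist() == [[1, 1], [1, 1]]


class TestExpandDuplicates:
    def test_counts_become_ranked_items(self):
        ds = records("GGAGGAGAUGGUGGAGAUGCCUGGAGACUAG")  # alpha twice, beta once
        table = build_occurrence_table(
            ds, [fs("GGAGAUG", {"s1"}), fs("UGGAGACU", {"s1"})]
        )
        tx = expand_duplicates(table)
        assert tx["s1"] == frozenset(
            {("GGAGAUG", 1), ("GGAGAUG", 2), ("UGGAGACU", 1)}
        )

    def test_all_zero_row_is_empty(self):
        ds = records("UUUU")
        table = build_occurrence_table(ds, [fs("ACG", set())])
        assert expand_duplicates(table)["s1"] == frozenset()

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.dictionaries(st.sampled_from("abcdef"), st.integers(0, 4), max_size=6))
    def test_lossless_reconstruction(self, row_counts):
        from seqtuples.tuples import OccurrenceTable

        counts = {"r": {s: n for s, n in row_counts.items() if n}}
        table = OccurrenceTable(("r",), tuple(row_counts), counts)
        items = expand_duplicates(table)["r"]
        recon = {}
        for sym, k in items:
            recon[sym] = max(recon.get(sym, 0), k)
        assert recon == counts["r"]


class TestMineClosedCombinations:
    def test_only_maximal_composite_kept(self):
        # {a}, {b}, {a,b} all supported by the same two sequences
        tx = {
            "ID_i": frozenset({("a", 1), ("b", 1)}),
            "ID_j": frozenset({("a", 1), ("b", 1)}),
        }
        out = mine_closed_combinations(tx, min_support=2)
        assert out == [
            SymbolCombination(
                members=(("a", 1), ("b", 1)),
                support_ids=frozenset({"ID_i", "ID_j"}),
            )
        ]

    def test_singleton_emitted_iff_supported(self):
        tx = {"t1": frozenset({("a", 1)}), "t2": frozenset()}
        out = mine_closed_combinations(tx, min_support=1)
        assert [c.members for c in out] == [(("a", 1),)]
        assert mine_closed_combinations(tx, min_support=2) == []

    def test_min_support_below_one_rejected(self):
        with pytest.raises(ConfigurationError):
            mine_closed_combinations({}, 0)

    def test_matches_powerset_oracle_on_random_tables(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            nitems = int(rng.integers(2, 9))
            ntrans = int(rng.integers(2, 10))
            syms = [chr(97 + i) for i in range(nitems)]
            tx = {
                f"t{j}": frozenset((s, 1) for s in syms if rng.random() < 0.5)
                for j in range(ntrans)
            }
            minsup = int(rng.integers(1, 4))
            mined = mine_closed_combinations(tx, minsup)
            got = {
                (
                    frozenset(
                        (sym, k) for sym, mult in c.members for k in range(1, mult + 1)
                    ),
                    c.support_ids,
                )
                for c in mined
            }
            assert got == powerset_closed_itemsets(tx, minsup)

    def test_duplicate_ranks_match_multiset_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            nsym = int(rng.integers(1, 5))
            nrows = int(rng.integers(2, 8))
            syms = [chr(97 + i) for i in range(nsym)]
            rows = {
                f"r{j}": {s: int(rng.integers(0, 4)) for s in syms}
                for j in range(nrows)
            }
            tx = {
                rid: frozenset(
                    (s, k) for s, n in row.items() for k in range(1, n + 1)
                )
                for rid, row in rows.items()
            }
            minsup = int(rng.integers(1, 4))
            mined = {
                (c.members, c.support_ids)
                for c in mine_closed_combinations(tx, minsup)
            }
            oracle = {
                (tuple(sorted(ms)), supp)
                for ms, supp in closed_multisets(rows, minsup, 3)
            }
            assert mined == oracle


class TestDeriveOrderedTuples:
    def test_worked_example_sequence_orders_the_pair(self):
        ds = records("GGAGGAGAUGGGGUCCUGGAGACUAAG")
        combo = SymbolCombination(
            members=(("GGAGAUG", 1), ("UGGAGACU", 1)), support_ids=frozenset({"s1"})
        )
        out = derive_ordered_tuples([combo], ds, tuple_min_frequency=1)
        assert [(t.members, t.frequency) for t in out] == [
            (("GGAGAUG", "UGGAGACU"), 1)
        ]

    def test_single_symbol_tuple_frequency_is_occurrence_count(self):
        ds = records("ACGTTACGTTACG", "ACGAA")
        combo = SymbolCombination(
            members=(("ACG", 1),), support_ids=frozenset({"s1", "s2"})
        )
        out = derive_ordered_tuples([combo], ds, tuple_min_frequency=1)
        assert out[0].frequency == 4

    def test_opposite_orders_counted_separately(self):
        a, b = "GAUCGGAUCCAU", "GGCAUUCGAUGC"
        fwd = PlantedTupleSpec(members=(a, b), gap_range=(4, 9), exact_fraction=0.5)
        rev = PlantedTupleSpec(members=(b, a), gap_range=(4, 9), exact_fraction=0.5)
        ds, _ = generate_synthetic(
            GeneratorConfig(20, 50, RNA, (fwd, rev), seed=99)
        )
        combo = SymbolCombination(
            members=((a, 1), (b, 1)),
            support_ids=frozenset(r.id for r in ds),
        )
        out = derive_ordered_tuples([combo], ds, tuple_min_frequency=1)
        freqs = {t.members: t.frequency for t in out}
        assert freqs == {(a, b): 10, (b, a): 10}

    def test_gap_distance_does_not_matter(self):
        a, b = "GAUCGGAUCCAU", "GGCAUUCGAUGC"
        tuples_by_gap = {}
        for gap in (5, 500):
            spec = PlantedTupleSpec(
                members=(a, b), gap_range=(gap, gap), exact_fraction=0.4
            )
            ds, _ = generate_synthetic(
                GeneratorConfig(30, 60, RNA, (spec,), seed=7)
            )
            cfg = MinerConfig(support_ratio=0.3, min_len=10, max_len=12)
            tuples_by_gap[gap] = {
                (t.members, t.frequency) for t in discover_tuples(ds, cfg)
            }
        assert ((a, b), 12) in tuples_by_gap[5]
        assert tuples_by_gap[5] == tuples_by_gap[500]

    def test_permutation_frequencies_sum_to_total_placements(self):
        rng = np.random.default_rng(3)
        ds = records(
            *(
                "".join(rng.choice(list("AC"), 30))
                for _ in range(10)
            )
        )
        multiset = Counter({"ACA": 1, "CC": 1})
        combo = SymbolCombination(
            members=(("ACA", 1), ("CC", 1)),
            support_ids=frozenset(r.id for r in ds),
        )
        out = derive_ordered_tuples([combo], ds, tuple_min_frequency=1)
        total = sum(
            len(multiset_placements(r.residues, multiset)) for r in ds
        )
        assert sum(t.frequency for t in out) == total


def test_count_ordered_placements():
    assert count_ordered_placements("ACG--TTG", ("ACG", "TTG")) == 1
    assert count_ordered_placements("TTGACG", ("ACG", "TTG")) == 0
    assert count_ordered_placements("ACGTTGACGTTG", ("ACG", "TTG")) == 2
    assert count_ordered_placements("AAAA", ("AA",)) == 2
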