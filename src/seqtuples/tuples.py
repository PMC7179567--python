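"""Co-occurrence mining and ordered frequent-sequence tuples.

Three stages:

1. An occurrence table: rows are sequences, columns are frequent
   subsequences, cells count leftmost-greedy non-overlapping exact
   occurrences.
2. Closed frequent combinations of subsequence symbols, with duplicates
   allowed: a column count of n for symbol a becomes presence items
   {a, 2a, ..., na}, and closed frequent itemsets are enumerated over those
   items with a stack-based depth-first search (no call-stack recursion, so
   very large symbol sets cannot overflow the interpreter stack).
3. Ordered tuples: each combination is re-scanned against the original
   sequences; every exact in-order non-overlapping placement records one
   observed permutation, identical permutations are pooled, and their
   occurrence counts become tuple frequencies.

Gaps between the members of a tuple are unbounded by design: the distance
between collaborating sites carries no weight here.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .errors import ConfigurationError
from .miner import FrequentSubsequence, count_nonoverlapping
from .seqio import SequenceRecord

__all__ = [
    "OccurrenceTable",
    "SymbolCombination",
    "FrequentTuple",
    "build_occurrence_table",
    "expand_duplicates",
    "mine_closed_combinations",
    "derive_ordered_tuples",
    "count_ordered_placements",
]

# an item is (symbol, k): "symbol occurs at least k times in the sequence"
Item = tuple


@dataclass(frozen=True)
class OccurrenceTable:
    """Sparse sequence x subsequence occurrence-count table."""

    row_ids: tuple
    columns: tuple  # residue strings of the frequent subsequences
    counts: dict  # row id -> {column string: positive count}

    def cell(self, row_id: str, column: str) -> int:
        return self.counts.get(row_id, {}).get(column, 0)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(0, index=list(self.row_ids), columns=list(self.columns))
        for rid, row in self.counts.items():
            for col, n in row.items():
                df.at[rid, col] = n
        return df


@dataclass(frozen=True)
class SymbolCombination:
    """A closed frequent multiset of subsequence symbols.

    ``members`` maps each symbol (residue string) to its multiplicity;
    ``support_ids`` is the set of sequences containing the whole multiset
    under the at-least-k occurrence rule.
    """

    members: tuple  # sorted tuple of (symbol, multiplicity)
    support_ids: frozenset

    @property
    def multiset(self) -> Counter:
        return Counter(dict(self.members))

    @property
    def support(self) -> int:
        return len(self.support_ids)


@dataclass(frozen=True)
class FrequentTuple:
    """An ordered tuple of subsequences with its exact-occurrence frequency."""

    members: tuple  # residue strings, left-to-right order
    frequency: int


def build_occurrence_table(
    dataset: list[SequenceRecord], subsequences: list[FrequentSubsequence]
) -> OccurrenceTable:
    """Count non-overlapping exact occurrences of each subsequence per row."""
    columns = tuple(f.residues for f in subsequences)
    counts: dict = {}
    for rec in dataset:
        row = {}
        for col in columns:
            n = count_nonoverlapping(col, rec.residues)
            if n:
                row[col] = n
        counts[rec.id] = row
    return OccurrenceTable(
        row_ids=tuple(rec.id for rec in dataset), columns=columns, counts=counts
    )


def expand_duplicates(table: OccurrenceTable) -> dict:
    """Translate occurrence counts into presence items with duplicate ranks.

    A count of n for symbol a yields items (a,1), (a,2), ..., (a,n); item
    (a,k) is present iff a occurs at least k times.  The mapping is lossless:
    the count is recoverable as the largest k present.
    """
    transactions: dict = {}
    for rid in table.row_ids:
        items = set()
        for col, n in table.counts.get(rid, {}).items():
            for k in range(1, n + 1):
                items.add((col, k))
        transactions[rid] = frozenset(items)
    return transactions


def mine_closed_combinations(transactions: dict, min_support: int) -> list[SymbolCombination]:
    """Enumerate closed frequent itemsets over duplicate-ranked items.

    Closedness uses support-set equality: an itemset is kept iff no proper
    superset occurs in exactly the same sequences.  The lattice is explored
    depth-first with an explicit stack using prefix-preserving closure
    extension, so each closed set is generated exactly once.
    """
    if min_support < 1:
        raise ConfigurationError("min_support must be >= 1")

    all_ids = frozenset(transactions)
    tidsets: dict = {}
    for rid, items in transactions.items():
        for item in items:
            tidsets.setdefault(item, set()).add(rid)
    # order: descending support, ties lexicographic on (symbol, rank)
    items = sorted(tidsets, key=lambda it: (-len(tidsets[it]), it))
    items = [it for it in items if len(tidsets[it]) >= min_support]
    tid = [frozenset(tidsets[it]) for it in items]
    index = {it: i for i, it in enumerate(items)}
    m = len(items)

    def closure(T: frozenset) -> frozenset:
        return frozenset(i for i in range(m) if T <= tid[i])

    results: list[tuple] = []
    root_T = all_ids
    root_C = closure(root_T) if len(root_T) >= min_support else frozenset()
    stack = [(root_C, root_T, -1)]
    if root_C and len(root_T) >= min_support:
        results.append((root_C, root_T))
    while stack:
        C, T, core = stack.pop()
        for i in range(m - 1, core, -1):
            if i in C:
                continue
            T2 = T & tid[i]
            if len(T2) < min_support:
                continue
            C2 = closure(T2)
            # prefix-preserving check: no new item below the extension point
            if any(j < i and j not in C for j in C2):
                continue
            results.append((C2, T2))
            stack.append((C2, T2, i))

    combos = []
    for C, T in results:
        mult: dict = {}
        for i in C:
            sym, k = items[i]
            mult[sym] = max(mult.get(sym, 0), k)
        combos.append(
            SymbolCombination(members=tuple(sorted(mult.items())), support_ids=T)
        )
    combos.sort(key=lambda c: c.members)
    return combos


def _multiset_placements(sequence: str, multiset: Counter) -> list[tuple]:
    """All leftmost-greedy in-order non-overlapping placements of a multiset.

    Scans left to right; at each step the earliest-starting remaining member
    is placed (ties broken toward the longest member).  Each completed
    placement yields the permutation of members in observed order; scanning
    then restarts after it for further placements.
    """
    placements = []
    remaining = Counter(multiset)
    perm: list = []
    pos = 0
    n = len(sequence)
    while pos <= n:
        best_q = None
        best_m = None
        for mstr, cnt in remaining.items():
            if cnt <= 0:
                continue
            q = sequence.find(mstr, pos)
            if q < 0:
                continue
            if best_q is None or q < best_q or (q == best_q and len(mstr) > len(best_m)):
                best_q, best_m = q, mstr
        if best_q is None:
            break
        perm.append(best_m)
        remaining[best_m] -= 1
        pos = best_q + len(best_m)
        if all(c == 0 for c in remaining.values()):
            placements.append(tuple(perm))
            perm = []
            remaining = Counter(multiset)
    return placements


def count_ordered_placements(sequence: str, members: tuple) -> int:
    """Exact in-order non-overlapping placements of an *ordered* tuple."""
    count = 0
    pos = 0
    while True:
        start = pos
        ok = True
        for mstr in members:
            q = sequence.find(mstr, start)
            if q < 0:
                ok = False
                break
            start = q + len(mstr)
        if not ok:
            return count
        count += 1
        pos = start


def derive_ordered_tuples(
    combinations: list[SymbolCombination],
    dataset: list[SequenceRecord],
    tuple_min_frequency: int = 1,
) -> list[FrequentTuple]:
    """Order each combination by re-scanning the original sequences.

    Every exact placement of a combination's members contributes one observed
    permutation; identical permutations are pooled across the dataset and
    counted, and permutations reaching ``tuple_min_frequency`` become tuples.
    """
    seq_by_id = {rec.id: rec.residues for rec in dataset}
    perm_counts: Counter = Counter()
    for combo in combinations:
        multiset = combo.multiset
        for rid in sorted(combo.support_ids):
            for perm in _multiset_placements(seq_by_id[rid], multiset):
                perm_counts[perm] += 1
    tuples = [
        FrequentTuple(members=perm, frequency=freq)
        for perm, freq in perm_counts.items()
        if freq >= tuple_min_frequency
    ]
    tuples.sort(key=lambda t: t.members)
    return tuples
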