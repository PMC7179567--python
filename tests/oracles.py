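"""Brute-force reference implementations used to cross-check the miners.

These deliberately enumerate everything (all substrings, the full powerset of
items, every placement) and stay independent of the package's algorithms.
"""

from collections import Counter, defaultdict
from itertools import combinations


def substring_supports(dataset, threshold, min_len, max_len):
    """All substrings with support >= threshold, by exhaustive enumeration."""
    supp = defaultdict(set)
    for rec in dataset:
        s = rec.residues
        seen = set()
        for i in range(len(s)):
            for L in range(min_len, min(max_len, len(s) - i) + 1):
                seen.add(s[i : i + L])
        for sub in seen:
            supp[sub].add(rec.id)
    return {sub: frozenset(ids) for sub, ids in supp.items() if len(ids) >= threshold}


def closed_strings(candidates):
    """Pairwise substring + support-set-equality closure, O(n^2)."""
    keep = set()
    for f in candidates:
        subsumed = any(
            f.residues != g.residues
            and f.residues in g.residues
            and f.support_ids == g.support_ids
            for g in candidates
        )
        if not subsumed:
            keep.add(f.residues)
    return keep


def powerset_closed_itemsets(transactions, min_support):
    """Closed frequent itemsets by full powerset enumeration (<= ~12 items)."""
    items = sorted({i for t in transactions.values() for i in t})
    frequent = {}
    for r in range(1, len(items) + 1):
        for subset in combinations(items, r):
            ss = frozenset(subset)
            supp = frozenset(rid for rid, t in transactions.items() if ss <= t)
            if len(supp) >= min_support:
                frequent[ss] = supp
    return {
        (ss, supp)
        for ss, supp in frequent.items()
        if not any(ss < ss2 and supp == s2 for ss2, s2 in frequent.items())
    }


def closed_multisets(count_rows, min_support, max_mult):
    """Closed frequent multisets over symbol counts, by full enumeration.

    ``count_rows``: {row id: {symbol: count}}.  A row supports a multiset iff
    it holds at least the required count of every symbol.
    """
    symbols = sorted({s for row in count_rows.values() for s in row})

    def supp(multiset):
        return frozenset(
            rid
            for rid, row in count_rows.items()
            if all(row.get(s, 0) >= k for s, k in multiset)
        )

    # enumerate all multisets with per-symbol multiplicity <= max_mult
    frequent = {}
    stack = [((), 0)]
    while stack:
        chosen, idx = stack.pop()
        if chosen:
            support = supp(chosen)
            if len(support) >= min_support:
                frequent[chosen] = support
            else:
                continue  # anti-monotone: no superset can be frequent
        if idx < len(symbols):
            for k in range(0, max_mult + 1):
                nxt = chosen + ((symbols[idx], k),) if k else chosen
                stack.append((nxt, idx + 1))
    # de-duplicate states pushed twice via the k=0 branch
    frequent = {tuple(sorted(ms)): s for ms, s in frequent.items()}

    def is_proper_super(a, b):  # a > b as multisets
        da, db = dict(a), dict(b)
        return a != b and all(da.get(s, 0) >= k for s, k in db.items())

    return {
        (ms, s)
        for ms, s in frequent.items()
        if not any(
            is_proper_super(ms2, ms) and s2 == s for ms2, s2 in frequent.items()
        )
    }


def multiset_placements(sequence, multiset):
    """Greedy leftmost in-order placements of a multiset of strings."""
    placements = []
    remaining = Counter(multiset)
    perm, pos = [], 0
    while True:
        candidates = []
        for m, c in remaining.items():
            if c > 0:
                q = sequence.find(m, pos)
                if q >= 0:
                    candidates.append((q, -len(m), m))
        if not candidates:
            return placements
        q, _, m = min(candidates)
        perm.append(m)
        remaining[m] -= 1
        pos = q + len(m)
        if not any(remaining.values()):
            placements.append(tuple(perm))
            perm, remaining = [], Counter(multiset)
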