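"""Closed frequent-substring mining.

A frequent subsequence is a gap-less substring that occurs in at least a
threshold number of dataset sequences (document frequency, counted via
support-ID sets).  Enumeration walks a prefix tree over all suffixes of all
sequences, level by level, depth-capped at ``max_len``; a substring of length
L+1 can only be frequent if its length-L prefix is (anti-monotonicity), which
prunes the search.

Closure then removes every substring that is a proper substring of another
retained candidate with an *identical* support set — only the super-string is
kept.  Substrings longer than ``keep_longest_above`` are exempt from
elimination so that long site-specific patterns always survive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .errors import ConfigurationError
from .seqio import SequenceRecord

__all__ = [
    "FrequentSubsequence",
    "MinerConfig",
    "mine_frequent_substrings",
    "closure_filter",
    "count_nonoverlapping",
]


def count_nonoverlapping(needle: str, haystack: str) -> int:
    """Leftmost-greedy count of non-overlapping occurrences of ``needle``."""
    count = 0
    pos = 0
    while True:
        pos = haystack.find(needle, pos)
        if pos < 0:
            return count
        count += 1
        pos += len(needle)


@dataclass(frozen=True)
class FrequentSubsequence:
    """A frequent substring with its supporting sequence-ID set.

    ``occurrence_total`` is the dataset-wide count of leftmost-greedy
    non-overlapping occurrences; it is carried along for tuple mining but
    plays no role in support thresholds.
    """

    residues: str
    support_ids: frozenset
    occurrence_total: int

    @property
    def support(self) -> int:
        return len(self.support_ids)


@dataclass(frozen=True)
class MinerConfig:
    """Thresholds for frequent-substring mining.

    Exactly one of ``min_support`` (absolute sequence count) or
    ``support_ratio`` (fraction of the dataset) must be set.  The support
    threshold depends on the heterogeneity of the data: homogeneous sets
    (e.g. one RNA family) tolerate high ratios, genome-scale binding-site
    sets need ratios as low as ~0.001.
    """

    min_support: Optional[int] = None
    support_ratio: Optional[float] = None
    min_len: int = 1
    max_len: int = 30
    keep_longest_above: Optional[int] = None

    def __post_init__(self):
        if (self.min_support is None) == (self.support_ratio is None):
            raise ConfigurationError(
                "exactly one of min_support / support_ratio must be set"
            )
        if self.min_support is not None and self.min_support < 1:
            raise ConfigurationError("min_support must be >= 1")
        if self.support_ratio is not None and not (0.0 < self.support_ratio <= 1.0):
            raise ConfigurationError("support_ratio must be in (0, 1]")
        if self.min_len < 1:
            raise ConfigurationError("min_len must be >= 1")
        if self.max_len < self.min_len:
            raise ConfigurationError("max_len must be >= min_len")

    def resolve_threshold(self, n_sequences: int) -> int:
        """Absolute support threshold for a dataset of ``n_sequences``."""
        if self.min_support is not None:
            threshold = self.min_support
        else:
            threshold = math.ceil(self.support_ratio * n_sequences)
        if threshold < 1:
            raise ConfigurationError(
                f"support threshold resolves to {threshold} sequences"
            )
        return threshold


def mine_frequent_substrings(
    dataset: list[SequenceRecord], config: MinerConfig
) -> list[FrequentSubsequence]:
    """Enumerate all frequent substrings (before closure filtering).

    Returns exactly the substrings with support >= threshold and length in
    ``[min_len, max_len]``, each with its full support-ID set, in
    lexicographic order.
    """
    if not dataset:
        raise ConfigurationError("dataset is empty")
    threshold = config.resolve_threshold(len(dataset))
    seqs = [(rec.id, rec.residues) for rec in dataset]

    results: list[FrequentSubsequence] = []
    # level 1: single residues
    frequent_prev: dict[str, frozenset] = {}
    level: dict[str, set] = {}
    for rec_id, s in seqs:
        for ch in set(s):
            level.setdefault(ch, set()).add(rec_id)
    frequent_prev = {
        sub: frozenset(ids) for sub, ids in level.items() if len(ids) >= threshold
    }
    _collect(results, frequent_prev, 1, config, seqs)

    length = 1
    while frequent_prev and length < config.max_len:
        length += 1
        level = {}
        prefixes = frequent_prev.keys()
        for rec_id, s in seqs:
            for i in range(len(s) - length + 1):
                sub = s[i : i + length]
                if sub[:-1] in prefixes:
                    level.setdefault(sub, set()).add(rec_id)
        frequent_prev = {
            sub: frozenset(ids) for sub, ids in level.items() if len(ids) >= threshold
        }
        _collect(results, frequent_prev, length, config, seqs)

    results.sort(key=lambda f: f.residues)
    return results


def _collect(results, frequent, length, config, seqs):
    if length < config.min_len or length > config.max_len:
        return
    seq_by_id = dict(seqs)
    for sub, ids in frequent.items():
        total = sum(count_nonoverlapping(sub, seq_by_id[i]) for i in ids)
        results.append(
            FrequentSubsequence(residues=sub, support_ids=ids, occurrence_total=total)
        )


def closure_filter(
    candidates: list[FrequentSubsequence],
    keep_longest_above: Optional[int] = None,
) -> list[FrequentSubsequence]:
    """Keep only closed candidates.

    A candidate is eliminated iff it is a proper substring of another
    candidate with an identical support-ID set (they occur in exactly the
    same sequences, so the super-string subsumes it).  Candidates longer
    than ``keep_longest_above`` are never eliminated.
    """
    by_support: dict[frozenset, list[FrequentSubsequence]] = {}
    for cand in candidates:
        by_support.setdefault(cand.support_ids, []).append(cand)

    kept: list[FrequentSubsequence] = []
    for group in by_support.values():
        for cand in group:
            if keep_longest_above is not None and len(cand.residues) > keep_longest_above:
                kept.append(cand)
                continue
            subsumed = any(
                cand.residues != other.residues and cand.residues in other.residues
                for other in group
            )
            if not subsumed:
                kept.append(cand)
    kept.sort(key=lambda f: f.residues)
    return kept
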