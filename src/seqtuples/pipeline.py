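"""End-to-end convenience drivers wiring the mining stages together."""

from __future__ import annotations

import logging
from typing import Optional

from .features import MutationProfile, build_profiles
from .matcher import DEFAULT_SCORING, ScoringScheme
from .miner import MinerConfig, closure_filter, mine_frequent_substrings
from .seqio import SequenceRecord
from .tuples import (
    FrequentTuple,
    build_occurrence_table,
    derive_ordered_tuples,
    expand_duplicates,
    mine_closed_combinations,
)

__all__ = ["discover_tuples", "feature_pipeline"]

log = logging.getLogger("seqtuples")


def discover_tuples(
    dataset: list[SequenceRecord],
    config: MinerConfig,
    combination_min_support: Optional[int] = None,
    tuple_min_frequency: Optional[int] = None,
) -> list[FrequentTuple]:
    """Mine -> closure -> occurrence table -> combinations -> ordered tuples.

    Combinations are mined at the same support threshold as single
    subsequences unless ``combination_min_support`` overrides it;
    ``tuple_min_frequency`` defaults to that same threshold.
    """
    threshold = config.resolve_threshold(len(dataset))
    candidates = mine_frequent_substrings(dataset, config)
    log.info("frequent substrings before closure: %d", len(candidates))
    closed = closure_filter(candidates, keep_longest_above=config.keep_longest_above)
    log.info("closed frequent subsequences: %d", len(closed))
    table = build_occurrence_table(dataset, closed)
    transactions = expand_duplicates(table)
    combo_support = combination_min_support or threshold
    combos = mine_closed_combinations(transactions, combo_support)
    log.info("closed symbol combinations: %d", len(combos))
    tuples = derive_ordered_tuples(
        combos, dataset, tuple_min_frequency=tuple_min_frequency or combo_support
    )
    log.info("ordered frequent tuples: %d", len(tuples))
    return tuples


def feature_pipeline(
    dataset: list[SequenceRecord],
    config: MinerConfig,
    scoring: ScoringScheme = DEFAULT_SCORING,
    combination_min_support: Optional[int] = None,
    tuple_min_frequency: Optional[int] = None,
) -> list[MutationProfile]:
    """Full discovery pipeline ending in mutation profiles."""
    tuples = discover_tuples(
        dataset, config, combination_min_support, tuple_min_frequency
    )
    profiles = build_profiles(tuples, dataset, scoring)
    log.info(
        "mutation profiles: %d (entries: %d)",
        len(profiles),
        sum(len(p.entries) for p in profiles),
    )
    return profiles
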