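"""Seeded synthetic sequence datasets with planted motif tuples.

The generator emulates the kind of inputs the mining pipeline consumes —
RNA/DNA sets in which an ordered tuple of motifs occurs in a controlled
fraction of sequences, separated by random-length gaps, with controlled
fractions of the plantings carrying a fixed mutation record (substitutions,
insertions, deletions in pattern coordinates).  Category counts are exact
(rounded once, then assignment shuffled), so the returned manifest is a
ground-truth oracle: it records every planted placement and record.

Backgrounds are rejection-sampled for two hygiene guarantees.  First, no
fragment of a planted motif (any substring as long as the shortest planted
form) may occur outside the planted member spans — this also excludes
junction artifacts, where a random gap base extends a planted motif into a
frequent spurious pattern.  Second, variant plantings must be unambiguous:
the canonical maximum-score explanation of the planted site must equal the
planted record (flanking bases can otherwise make an alternative alignment —
e.g. a substitution instead of a deletion — equally good).  Draws violating
either guarantee are redrawn, so manifest counts are exact ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
import numpy as np

from .errors import ConfigurationError
from .matcher import (
    ScoringScheme,
    apply_record,
    match_tuple,
    parse_record,
    serialize_record,
    tuple_events,
)
from .seqio import RNA, Alphabet, SequenceRecord

__all__ = ["PlantedTupleSpec", "GeneratorConfig", "generate_synthetic", "write_manifest"]

_MAX_REDRAWS = 200


@dataclass(frozen=True)
class PlantedTupleSpec:
    """One ordered motif tuple to plant.

    ``exact_fraction`` of all sequences receive the members verbatim, in
    order, with gap lengths drawn uniformly from ``gap_range``; each
    ``variants`` entry (mutation record, fraction) plants the mutated form
    instead.
    """

    members: tuple
    gap_range: tuple = (3, 12)
    exact_fraction: float = 0.0
    variants: tuple = ()  # ((record string, fraction), ...)

    def __post_init__(self):
        if not self.members:
            raise ConfigurationError("planted tuple needs at least one member")
        lo, hi = self.gap_range
        if lo < 0 or hi < lo:
            raise ConfigurationError("gap_range must satisfy 0 <= lo <= hi")
        for record, frac in self.variants:
            parse_record(record)
            if not (0.0 <= frac <= 1.0):
                raise ConfigurationError("variant fractions must be in [0, 1]")
        if not (0.0 <= self.exact_fraction <= 1.0):
            raise ConfigurationError("exact_fraction must be in [0, 1]")


@dataclass(frozen=True)
class GeneratorConfig:
    n_sequences: int = 100
    sequence_length: int = 100
    alphabet: Alphabet = RNA
    planted: tuple = ()  # PlantedTupleSpec, ...
    seed: int = 0

    def __post_init__(self):
        if self.n_sequences < 1:
            raise ConfigurationError("n_sequences must be >= 1")
        if self.sequence_length < 1:
            raise ConfigurationError("sequence_length must be >= 1")
        total = sum(
            spec.exact_fraction + sum(f for _, f in spec.variants)
            for spec in self.planted
        )
        if total > 1.0 + 1e-9:
            raise ConfigurationError(
                f"planted fractions sum to {total:.3f} > 1"
            )
        for spec in self.planted:
            if max(len(m) for m in spec.members) > self.sequence_length:
                raise ConfigurationError(
                    "planted members longer than sequence_length"
                )


def _category_counts(config: GeneratorConfig) -> list:
    """(spec index, record-or-None, count) per category, rounded once."""
    cats = []
    for si, spec in enumerate(config.planted):
        cats.append((si, None, int(round(spec.exact_fraction * config.n_sequences))))
        for record, frac in spec.variants:
            cats.append((si, record, int(round(frac * config.n_sequences))))
    if sum(c for _, _, c in cats) > config.n_sequences:
        raise ConfigurationError("rounded category counts exceed n_sequences")
    return cats


def generate_synthetic(config: GeneratorConfig):
    """Generate sequences plus a ground-truth manifest.

    Returns ``(records, manifest)``: records in id order, and a JSON-friendly
    manifest with one entry per sequence (category, planted record, member
    start positions) and aggregate per-category counts.
    """
    rng = np.random.default_rng(config.seed)
    chars = np.array(list(config.alphabet.characters))

    # strings whose accidental occurrence would corrupt the ground truth
    watch: set = set()
    for spec in config.planted:
        watch.update(spec.members)
        for record, _ in spec.variants:
            watch.update(apply_record(spec.members, parse_record(record)))
    watch_kmers: set = set()
    if watch:
        k = min(len(w) for w in watch)
        for w in watch:
            for i in range(len(w) - k + 1):
                watch_kmers.add(w[i : i + k])

    assignments: list = []
    for si, record, count in _category_counts(config):
        assignments.extend([(si, record)] * count)
    assignments.extend([None] * (config.n_sequences - len(assignments)))
    order = rng.permutation(len(assignments))
    assignments = [assignments[i] for i in order]

    def background(n: int) -> str:
        return "".join(rng.choice(chars, size=n)) if n > 0 else ""

    records = []
    entries = []
    counts: dict = {}
    width = len(str(config.n_sequences))
    for i, assign in enumerate(assignments):
        rec_id = f"seq{i:0{width}d}"
        if assign is None:
            seq = _draw_background_seq(background, config.sequence_length, watch_kmers)
            entries.append(
                {"id": rec_id, "category": "background", "tuple_index": None,
                 "record": None, "member_positions": None}
            )
            counts["background"] = counts.get("background", 0) + 1
        else:
            si, record = assign
            spec = config.planted[si]
            seq, positions = _draw_planted_seq(
                background, rng, config, spec, record, watch_kmers
            )
            category = "exact" if record is None else "variant"
            entries.append(
                {"id": rec_id, "category": category, "tuple_index": si,
                 "record": record, "member_positions": positions}
            )
            key = f"tuple{si}:" + ("exact" if record is None else record)
            counts[key] = counts.get(key, 0) + 1
        records.append(SequenceRecord(id=rec_id, residues=seq))

    manifest = {
        "seed": config.seed,
        "n_sequences": config.n_sequences,
        "alphabet": config.alphabet.name,
        "planted": [
            {"members": list(spec.members), "gap_range": list(spec.gap_range)}
            for spec in config.planted
        ],
        "counts": counts,
        "sequences": entries,
    }
    return records, manifest


def _fragments_confined(seq: str, spans: list, watch_kmers: set) -> bool:
    """True if every occurrence of a watched motif fragment lies inside a
    planted member span."""
    for w in watch_kmers:
        pos = seq.find(w)
        while pos >= 0:
            end = pos + len(w)
            if not any(a <= pos and end <= b for a, b in spans):
                return False
            pos = seq.find(w, pos + 1)
    return True


def _member_counts_ok(seq: str, expected: dict) -> bool:
    for m, want in expected.items():
        n = 0
        pos = seq.find(m)
        while pos >= 0:
            n += 1
            pos = seq.find(m, pos + 1)  # overlapping count: strictest check
        if n != want:
            return False
    return True


def _draw_background_seq(background, length: int, watch_kmers: set) -> str:
    for _ in range(_MAX_REDRAWS):
        seq = background(length)
        if _fragments_confined(seq, [], watch_kmers):
            return seq
    raise ConfigurationError(
        "could not draw a background free of planted motif fragments; "
        "sequences too long or motifs too short"
    )


def _draw_planted_seq(background, rng, config, spec, record, watch_kmers):
    planted_members = (
        spec.members if record is None
        else apply_record(spec.members, parse_record(record))
    )
    expected: dict = {}
    for m in planted_members:
        expected[m] = expected.get(m, 0) + 1
    lo, hi = spec.gap_range
    for _ in range(_MAX_REDRAWS):
        gaps = [int(rng.integers(lo, hi + 1)) for _ in range(len(planted_members) - 1)]
        content_parts = []
        offsets = []
        off = 0
        for k, m in enumerate(planted_members):
            offsets.append(off)
            content_parts.append(m)
            off += len(m)
            if k < len(gaps):
                content_parts.append(background(gaps[k]))
                off += gaps[k]
        content = "".join(content_parts)
        total = max(config.sequence_length, len(content))
        left = int(rng.integers(0, total - len(content) + 1))
        right = total - len(content) - left
        seq = background(left) + content + background(right)
        spans = [
            (left + o, left + o + len(m)) for o, m in zip(offsets, planted_members)
        ]
        if not _fragments_confined(seq, spans, watch_kmers):
            continue
        if not _member_counts_ok(seq, expected):
            continue
        if record is not None and not _record_unambiguous(spec.members, seq, record):
            continue
        return seq, [left + o for o in offsets]
    raise ConfigurationError(
        "could not plant motifs without accidental extra occurrences or "
        "ambiguous variant context"
    )


def _record_unambiguous(members: tuple, seq: str, record: str) -> bool:
    """True if the best explanation of the planted site is the planted record."""
    events = parse_record(record)
    canonical = serialize_record(events)
    scoring = ScoringScheme(min_score=-float(max(len(events), 1)))
    hits = match_tuple(members, seq, scoring)
    return hits is not None and serialize_record(tuple_events(hits)) == canonical


def write_manifest(manifest: dict, path) -> None:
    with Path(path).open("w") as handle:
        json.dump(manifest, handle, indent=1, sort_keys=True)
        handle.write("\n")
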