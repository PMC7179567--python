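"""Approximate matching of patterns and tuples under the edit-distance metric.

A pattern (frequent subsequence) is aligned against every substring of a
text; matching a residue scores zero and each substitution, insertion or
deletion event scores a negative penalty.  The alignment with the maximum
score is retained; if even the best score falls below ``min_score`` the match
is a failure.  The search is the score-maximizing traversal of an edit-event
automaton, implemented as a pruned dynamic program over pattern states.

Edit events are anchored to 0-based *pattern* coordinates:

* ``SUB m p x y`` — member m, pattern position p, pattern base x replaced by
  observed base y;
* ``DEL m p x``   — pattern base x at position p absent from the text;
* ``INS m p y``   — observed base y inserted in front of pattern position p.

An event list serializes to a compact mutation record such as
``SUB 0 5 U C DEL 1 6 C``, which round-trips bit-exactly through
``parse_record``/``serialize_record``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .errors import ConfigurationError, RecordParseError

__all__ = [
    "ScoringScheme",
    "EditEvent",
    "MatchResult",
    "approx_match",
    "match_tuple",
    "serialize_record",
    "parse_record",
    "canonical_record",
    "apply_record",
]

_KIND_RANK = {"SUB": 0, "DEL": 1, "INS": 2}  # tie-break preference order


@dataclass(frozen=True)
class ScoringScheme:
    """Event scores: matches are free, every edit costs a negative penalty.

    ``min_score`` is the failure threshold; with the unit default penalties
    and ``min_score=-2`` at most two edit events are tolerated per pattern.
    """

    sub_penalty: float = -1.0
    ins_penalty: float = -1.0
    del_penalty: float = -1.0
    min_score: float = -2.0
    match_score: float = 0.0  # fixed by construction

    def __post_init__(self):
        if self.match_score != 0.0:
            raise ConfigurationError("match_score must be 0")
        if not (self.sub_penalty < 0 and self.ins_penalty < 0 and self.del_penalty < 0):
            raise ConfigurationError("all edit penalties must be negative")
        if self.min_score > 0:
            raise ConfigurationError("min_score must be <= 0")


DEFAULT_SCORING = ScoringScheme()


@dataclass(frozen=True)
class EditEvent:
    kind: str  # SUB | INS | DEL
    member_index: int
    position: int  # 0-based position in the pattern
    pattern_base: Optional[str] = None  # SUB, DEL
    observed_base: Optional[str] = None  # SUB, INS

    def __post_init__(self):
        if self.kind not in _KIND_RANK:
            raise ConfigurationError(f"unknown event kind {self.kind!r}")


@dataclass(frozen=True)
class MatchResult:
    """Best alignment of one pattern against a text region."""

    score: float
    events: tuple  # EditEvent, in canonical order
    span: tuple  # (start, end) half-open in the text

    @property
    def exact(self) -> bool:
        return not self.events


def _sort_events(events) -> tuple:
    # stable: simultaneous insertions at one position keep text order
    return tuple(sorted(events, key=lambda e: (e.member_index, e.position, e.kind)))


def serialize_record(events) -> str:
    """Canonical compact mutation record for an event list ('' if exact)."""
    parts = []
    for ev in _sort_events(events):
        if ev.kind == "SUB":
            parts.extend(["SUB", str(ev.member_index), str(ev.position),
                          ev.pattern_base, ev.observed_base])
        elif ev.kind == "DEL":
            parts.extend(["DEL", str(ev.member_index), str(ev.position),
                          ev.pattern_base])
        else:  # INS
            parts.extend(["INS", str(ev.member_index), str(ev.position),
                          ev.observed_base])
    return " ".join(parts)


canonical_record = serialize_record


def parse_record(text: str) -> tuple:
    """Parse a compact mutation record back into edit events."""
    tokens = text.split()
    events = []
    i = 0

    def take(n: int) -> list:
        nonlocal i
        if i + n > len(tokens):
            raise RecordParseError("truncated mutation record", i)
        out = tokens[i : i + n]
        i += n
        return out

    while i < len(tokens):
        kind = tokens[i]
        if kind == "SUB":
            _, member, pos, pb, ob = take(5)
        elif kind == "DEL":
            _, member, pos, pb = take(4)
            ob = None
        elif kind == "INS":
            _, member, pos, ob = take(4)
            pb = None
        else:
            raise RecordParseError(f"unknown event kind {kind!r}", i)
        try:
            member_i, pos_i = int(member), int(pos)
        except ValueError:
            raise RecordParseError("member index and position must be integers", i - 1)
        events.append(EditEvent(kind, member_i, pos_i, pb, ob))
    return tuple(events)


def apply_record(members: tuple, events) -> tuple:
    """Apply edit events to a tuple of pattern strings, yielding the variant.

    Inverse of matching: the returned strings are what the pattern looks like
    in a text exhibiting exactly this mutation record.  Used by the synthetic
    generator to plant variants.
    """
    out = []
    for idx, member in enumerate(members):
        s = list(member)
        delta = 0
        evs = sorted(
            (e for e in events if e.member_index == idx),
            key=lambda e: (e.position, 0 if e.kind == "INS" else 1),
        )
        for ev in evs:
            p = ev.position + delta
            if ev.kind == "SUB":
                if member[ev.position] != ev.pattern_base:
                    raise ConfigurationError(
                        f"SUB pattern base mismatch at member {idx} position {ev.position}"
                    )
                s[p] = ev.observed_base
            elif ev.kind == "DEL":
                if member[ev.position] != ev.pattern_base:
                    raise ConfigurationError(
                        f"DEL pattern base mismatch at member {idx} position {ev.position}"
                    )
                del s[p]
                delta -= 1
            else:  # INS: new base in front of this position
                s.insert(p, ev.observed_base)
                delta += 1
        out.append("".join(s))
    return tuple(out)


# ---------------------------------------------------------------------------
# alignment search


def _state_key(score, events):
    # maximize score, then fewer events, then SUB > DEL > INS along the path
    return (score, -len(events), tuple(-_KIND_RANK[e.kind] for e in events))


def _align_from(pattern, text, start, sc, member_index):
    """Best full-pattern alignment beginning at text offset ``start``.

    Returns (key, events, end) or None.  States are pattern positions; score
    pruning at ``min_score`` keeps the frontier narrow.
    """
    m = len(pattern)

    def del_closure(states):
        for j in range(m):
            if j in states:
                score, events = states[j]
                s2 = score + sc.del_penalty
                if s2 >= sc.min_score:
                    ev = EditEvent("DEL", member_index, j, pattern[j], None)
                    cand = (s2, events + (ev,))
                    old = states.get(j + 1)
                    if old is None or _state_key(*cand) > _state_key(*old):
                        states[j + 1] = cand

    best = None  # (key, events, end)
    states = {0: (0.0, ())}
    del_closure(states)
    if m in states:
        score, events = states[m]
        best = (_state_key(score, events), events, start)
    t = start
    while states and t < len(text):
        ch = text[t]
        nxt: dict = {}

        def push(j, score, events):
            old = nxt.get(j)
            if old is None or _state_key(score, events) > _state_key(*old):
                nxt[j] = (score, events)

        for j, (score, events) in states.items():
            if j < m:
                if pattern[j] == ch:
                    push(j + 1, score, events)
                else:
                    s2 = score + sc.sub_penalty
                    if s2 >= sc.min_score:
                        ev = EditEvent("SUB", member_index, j, pattern[j], ch)
                        push(j + 1, s2, events + (ev,))
                s3 = score + sc.ins_penalty
                if s3 >= sc.min_score:
                    ev = EditEvent("INS", member_index, j, None, ch)
                    push(j, s3, events + (ev,))
        del_closure(nxt)
        if m in nxt:
            score, events = nxt[m]
            key = _state_key(score, events)
            if best is None or key > best[0]:
                best = (key, events, t + 1)
        states = nxt
        t += 1
    return best


def approx_match(
    pattern: str,
    text: str,
    scoring: ScoringScheme = DEFAULT_SCORING,
    member_index: int = 0,
) -> Optional[MatchResult]:
    """Maximum-score alignment of ``pattern`` against any substring of ``text``.

    Ties are broken toward fewer events, then substitutions over deletions
    over insertions, then the leftmost span.  Returns None on failure (best
    score below ``min_score``).
    """
    if not pattern:
        raise ConfigurationError("pattern must be non-empty")
    best = None  # (key, events, span)
    for start in range(len(text) + 1):
        hit = _align_from(pattern, text, start, scoring, member_index)
        if hit is not None:
            key, events, end = hit
            if best is None or key > best[0]:
                best = (key, events, (start, end))
    if best is None:
        return None
    key, events, span = best
    return MatchResult(score=float(key[0]), events=_sort_events(events), span=span)


def match_tuple(
    members: tuple,
    text: str,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> Optional[list]:
    """Match the members of an ordered tuple left-to-right in ``text``.

    Members must appear in tuple order, non-overlapping, each individually
    satisfying ``min_score``; gaps of any size are permitted between members.
    Returns one MatchResult per member (spans in whole-text coordinates), or
    None if any member fails.
    """
    if not members:
        raise ConfigurationError("tuple must have at least one member")
    results = []
    pos = 0
    for idx, member in enumerate(members):
        hit = approx_match(member, text[pos:], scoring, member_index=idx)
        if hit is None:
            return None
        span = (hit.span[0] + pos, hit.span[1] + pos)
        results.append(MatchResult(score=hit.score, events=hit.events, span=span))
        pos = span[1]
    return results


def tuple_events(results: list) -> tuple:
    """Pooled, canonically ordered events of a whole-tuple match."""
    events = []
    for r in results:
        events.extend(r.events)
    return _sort_events(events)
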