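"""Mutation profiles, feature descriptors, libsvm export and PSSM conversion.

A mutation profile attaches, to each ordered frequent tuple, its exact
placement count over a profiling dataset plus the observed approximate
placements grouped by canonical mutation record.  The descriptor component of
a sequence for tuple j is then

* 1.0 if the tuple places exactly in the sequence,
* frequency(record) / exact_frequency if the best approximate placement's
  mutation record is present in the profile,
* 0 otherwise,

and the per-tuple components stack into the feature vector used for
classification.  Profiles also convert to position-specific scoring matrices
(one per tuple member) for motif comparison tools.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import ConfigurationError, ValidationError
from .matcher import (
    DEFAULT_SCORING,
    ScoringScheme,
    match_tuple,
    parse_record,
    serialize_record,
    tuple_events,
)
from .seqio import Alphabet, SequenceRecord, infer_alphabet
from .tuples import FrequentTuple, count_ordered_placements

__all__ = [
    "MutationProfile",
    "PSSM",
    "build_profiles",
    "encode_sequence",
    "encode_dataset",
    "write_libsvm",
    "to_pssm",
    "write_feature_file",
    "read_feature_file",
    "write_profile_file",
    "read_profile_file",
    "write_pssm_file",
]


@dataclass(frozen=True)
class MutationProfile:
    """Exact-placement frequency plus (mutation record, frequency) entries."""

    tuple: FrequentTuple
    exact_frequency: int
    entries: tuple  # sorted tuple of (record string, frequency >= 1)

    def entry_frequency(self, record: str) -> int:
        return dict(self.entries).get(record, 0)


@dataclass(frozen=True)
class PSSM:
    """Per-position residue counts (or frequencies) for one tuple member."""

    member: str
    alphabet: tuple
    matrix: np.ndarray  # rows = alphabet residues, columns = pattern positions


def build_profiles(
    tuples: list[FrequentTuple],
    dataset: list[SequenceRecord],
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> list[MutationProfile]:
    """Re-scan the dataset for each tuple and collect its mutation profile.

    Exact placements (counted with the same in-order non-overlapping rule as
    tuple mining) increment ``exact_frequency``.  A sequence without an exact
    placement is matched approximately; a successful match with at least one
    edit event increments the frequency of its canonical mutation record.
    """
    profiles = []
    for tup in tuples:
        exact = 0
        entry_counts: Counter = Counter()
        for rec in dataset:
            n = count_ordered_placements(rec.residues, tup.members)
            if n > 0:
                exact += n
                continue
            hits = match_tuple(tup.members, rec.residues, scoring)
            if hits is None:
                continue
            events = tuple_events(hits)
            if events:
                entry_counts[serialize_record(events)] += 1
        profiles.append(
            MutationProfile(
                tuple=tup,
                exact_frequency=exact,
                entries=tuple(sorted(entry_counts.items())),
            )
        )
    return profiles


def encode_sequence(
    sequence: SequenceRecord,
    profiles: list[MutationProfile],
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> np.ndarray:
    """Descriptor vector of a sequence: one component per profiled tuple."""
    if not profiles:
        raise ConfigurationError("profiles must be non-empty")
    values = np.zeros(len(profiles))
    text = sequence.residues
    for j, prof in enumerate(profiles):
        members = prof.tuple.members
        if count_ordered_placements(text, members) > 0:
            values[j] = 1.0
            continue
        hits = match_tuple(members, text, scoring)
        if hits is None:
            continue
        record = serialize_record(tuple_events(hits))
        freq = prof.entry_frequency(record)
        if freq and prof.exact_frequency > 0:
            component = freq / prof.exact_frequency
            if component > 1.0:
                warnings.warn(
                    f"component {component:.4g} exceeds 1 for tuple {members}: "
                    f"record frequency {freq} > exact frequency {prof.exact_frequency}"
                )
            values[j] = component
    return values


def encode_dataset(
    dataset: list[SequenceRecord],
    profiles: list[MutationProfile],
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> np.ndarray:
    return np.array([encode_sequence(rec, profiles, scoring) for rec in dataset])


def write_libsvm(vectors, labels, path) -> None:
    """Write labeled descriptor vectors in sparse libsvm format.

    One line per sequence: ``<label> <index>:<value> ...`` with 1-based
    ascending indices; zero components are omitted, so an all-zero vector
    yields a bare label.
    """
    vectors = np.asarray(vectors, dtype=float)
    if len(vectors) != len(labels):
        raise ValidationError(
            f"{len(vectors)} vectors but {len(labels)} labels"
        )
    if any(lab not in (1, -1) for lab in labels):
        raise ValidationError("labels must be +1 or -1")
    with Path(path).open("w") as handle:
        for vec, lab in zip(vectors, labels):
            parts = ["+1" if lab == 1 else "-1"]
            for idx in np.flatnonzero(vec):
                parts.append(f"{idx + 1}:{repr(float(vec[idx]))}")
            handle.write(" ".join(parts) + "\n")


def to_pssm(
    profile: MutationProfile,
    normalize: bool = False,
    pseudocount: float = 0.0,
    alphabet: Optional[Alphabet] = None,
) -> list[PSSM]:
    """Convert a mutation profile into one PSSM per tuple member.

    Every consensus base starts at ``exact_frequency``.  Each profile entry
    adds its frequency to the observed base of its substitutions and to the
    consensus base of every member position the entry does not touch;
    insertion and deletion events contribute nothing positionally, since a
    fixed-width matrix cannot represent indels.
    """
    if pseudocount < 0:
        raise ConfigurationError("pseudocount must be >= 0")
    if profile.exact_frequency == 0 and not profile.entries:
        raise ConfigurationError("profile is empty: no exact or approximate placements")
    members = profile.tuple.members
    if alphabet is None:
        alphabet = infer_alphabet(members)
    residues = alphabet.characters
    row = {ch: i for i, ch in enumerate(residues)}

    parsed = [(parse_record(rec), freq) for rec, freq in profile.entries]
    pssms = []
    for idx, member in enumerate(members):
        L = len(member)
        mat = np.zeros((len(residues), L), dtype=float)
        for p, base in enumerate(member):
            mat[row[base], p] = profile.exact_frequency
        for events, freq in parsed:
            touched = {e.position for e in events if e.member_index == idx}
            for e in events:
                if e.member_index == idx and e.kind == "SUB":
                    mat[row[e.observed_base], e.position] += freq
            for p, base in enumerate(member):
                if p not in touched:
                    mat[row[base], p] += freq
        mat += pseudocount
        if normalize:
            sums = mat.sum(axis=0)
            if np.any(sums == 0):
                raise ConfigurationError(
                    "cannot normalize: a column has zero total count"
                )
            mat = mat / sums
        pssms.append(PSSM(member=member, alphabet=tuple(residues), matrix=mat))
    return pssms


# ---------------------------------------------------------------------------
# file dialects


def write_feature_file(tuples: list[FrequentTuple], path) -> None:
    """One tuple per line, members tab-separated."""
    with Path(path).open("w") as handle:
        for tup in tuples:
            handle.write("\t".join(tup.members) + "\n")


def read_feature_file(path) -> list[tuple]:
    out = []
    with Path(path).open() as handle:
        for line in handle:
            line = line.rstrip("\n")
            if line:
                out.append(tuple(line.split("\t")))
    return out


def write_profile_file(profiles: list[MutationProfile], path) -> None:
    """One block per tuple: a TUPLE header, then one entry line per record.

    Header: ``TUPLE <member> ... FREQ <exact_frequency>``; each entry line is
    the mutation record followed by its frequency.  Entries are written in
    sorted record order, so writing is deterministic and write(read(f))
    reproduces f byte for byte.
    """
    with Path(path).open("w") as handle:
        for k, prof in enumerate(profiles):
            if k:
                handle.write("\n")
            handle.write(
                "TUPLE " + " ".join(prof.tuple.members)
                + f" FREQ {prof.exact_frequency}\n"
            )
            for record, freq in sorted(prof.entries):
                handle.write(f"{record} {freq}\n")


def read_profile_file(path) -> list[MutationProfile]:
    profiles = []
    members: Optional[tuple] = None
    exact = 0
    entries: list = []

    def flush():
        if members is not None:
            profiles.append(
                MutationProfile(
                    tuple=FrequentTuple(members=members, frequency=exact),
                    exact_frequency=exact,
                    entries=tuple(sorted(entries)),
                )
            )

    with Path(path).open() as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            tokens = line.split()
            if tokens[0] == "TUPLE":
                flush()
                if len(tokens) < 4 or tokens[-2] != "FREQ":
                    raise ValidationError(
                        f"{path}:{lineno}: malformed TUPLE header"
                    )
                members = tuple(tokens[1:-2])
                exact = int(tokens[-1])
                entries = []
            else:
                if members is None:
                    raise ValidationError(
                        f"{path}:{lineno}: entry before any TUPLE header"
                    )
                record = " ".join(tokens[:-1])
                parse_record(record)  # validates the token stream
                entries.append((record, int(tokens[-1])))
    flush()
    return profiles


def write_pssm_file(pssms_per_tuple: list, path) -> None:
    """Plain-text PSSM blocks: a MOTIF header naming the member, then the
    count matrix with residues as rows and positions as columns."""
    with Path(path).open("w") as handle:
        for t_idx, pssms in enumerate(pssms_per_tuple):
            for m_idx, pssm in enumerate(pssms):
                handle.write(f"MOTIF tuple{t_idx} member{m_idx} {pssm.member}\n")
                L = pssm.matrix.shape[1]
                handle.write("POS\t" + "\t".join(str(p) for p in range(L)) + "\n")
                for r, ch in enumerate(pssm.alphabet):
                    vals = "\t".join(_fmt(v) for v in pssm.matrix[r])
                    handle.write(f"{ch}\t{vals}\n")
                handle.write("\n")


def _fmt(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else format(v, ".6g")
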