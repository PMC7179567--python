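# Methods

This note records the model behind `seqtuples`, the parameters that matter,
the numerical and design choices made where the procedure was genuinely open,
and what the synthetic benchmarks do and do not demonstrate.

## Model and assumptions

The unit of signal is an **ordered tuple of gap-less motifs**. The model
assumes that functional sequences in a family share (i) short exact
substrings ("frequent subsequences") present in at least a threshold fraction
of the family, (ii) co-occurrence of several such substrings in a conserved
left-to-right order, with **no constraint on the distance** between them, and
(iii) a small set of recurrent point mutations (substitutions, single-base
insertions and deletions) of those substrings whose observed frequencies
carry information. No reverse-complement search is performed: the tool
operates on the given strand only, so strand handling is the caller's
responsibility.

Support is counted per sequence (document frequency), not per occurrence:
the mining trie stores the set of sequence IDs under each node, and closure
compares those sets. Occurrence totals are still recorded because tuple
frequencies are occurrence-based (see below).

## Mining

* **Frequent substrings** are enumerated level-by-level over a prefix tree of
  all suffixes, depth-capped at `max_len`; a length-(L+1) candidate is only
  counted if its length-L prefix is frequent. Output order is lexicographic
  for determinism.
* **Closure** removes a candidate iff it is a proper substring of another
  candidate with an *identical* support-ID set. Support-set equality — not
  mere frequency equality — is the criterion, because two patterns with equal
  counts in different sequences are genuinely different features.
  `keep_longest_above` exempts patterns longer than a bound from elimination,
  for applications where long site-specific patterns must always be reported.
* **Combinations.** Occurrence counts are translated into ranked presence
  items (count n for α → items α, 2α, …, nα; item kα present iff α occurs at
  least k times; the translation is lossless). Closed frequent itemsets over
  these items are enumerated with prefix-preserving closure extension,
  depth-first on an explicit stack (no interpreter recursion, so symbol sets
  in the thousands cannot overflow the call stack). Items are ordered by
  descending support, ties lexicographic — the standard heuristic, fixed for
  determinism.
* **Ordered tuples.** A combination is placed in a sequence greedily: scan
  left to right, always placing the earliest-starting remaining member (ties
  to the longest). Members of one placement never overlap — they represent
  distinct collaborating sites. Each complete placement contributes one
  permutation observation; scanning resumes after it, so one sequence can
  contribute several placements. Tuple frequency is therefore counted **per
  occurrence**, matching the definition of the encoder's denominator as "how
  often the tuple occurred in the data set"; combination support, by
  contrast, is presence-based (a sequence either holds the multiset or not).

## Approximate matching

Matching a pattern to a text region is a score-maximizing traversal of an
edit-event automaton, computed as a pruned dynamic program: matches score 0,
each substitution/insertion/deletion a negative penalty; the best-scoring
alignment of the *whole* pattern against *any* substring of the text is
returned, and anything below `min_score` is a failure. Defaults are unit
penalties (−1 each) with `min_score = −2`, i.e. at most two edit events per
pattern; the defaults are declared, configurable values — the appropriate cap
depends on pattern length and family divergence.

Numerical/tie choices, all fixed so that identical inputs give identical
results:

* Ties are broken toward fewer events, then substitutions over deletions over
  insertions (compared along the alignment path), then the leftmost span.
* Events are anchored to 0-based pattern coordinates; an insertion stores the
  observed base inserted *in front of* its pattern position.
* Several events may fall on one pattern position (e.g. two inserted bases in
  front of it). Allowing this is required for the matcher to agree exactly
  with the edit-distance metric: there are pattern/text pairs whose only
  minimal explanation inserts two bases at the same position, and any
  one-event-per-position restriction would misreport them as more distant.
  Records stay canonical because events sort stably by (member, position,
  kind) with same-position insertions kept in text order.
* Tuple matching is greedy left-to-right: each member takes its best (then
  leftmost) match after the previous member's span. A non-greedy placement
  could in principle rescue rare cases a greedy one rejects; greediness was
  chosen for determinism and linear cost in the number of members.

With unit penalties the returned score is minus the infix edit distance
whenever a match exists — this is tested against an independent
edit-distance oracle (edlib in infix mode) over thousands of random pairs.

## Profiles, encoding, PSSM

* Profiling re-scans the dataset per tuple. A sequence with exact placements
  contributes all of them to `exact_frequency`; only sequences *without* an
  exact placement are matched approximately (exact placement takes
  precedence), and each contributes at most one record — that of its best
  approximate placement.
* The encoder's approximate component requires the query's canonical record
  to **equal** a recorded entry; near-miss records score 0. The denominator
  is the *profiling* dataset's exact frequency (relevant when discovery and
  profiling datasets differ); if it is 0 the component is 0. Components can
  exceed 1 when a variant outnumbers the exact form — this is allowed but
  flagged with a warning.
* PSSM conversion initializes every consensus base at `exact_frequency`,
  adds each entry's frequency to the observed base of its substitutions, and
  adds the entry frequency to the consensus base of every position the entry
  does not touch. Insertion and deletion events contribute nothing
  positionally: a fixed-width matrix cannot represent indels, and spreading
  their mass would distort the untouched columns. An optional pseudocount is
  added before optional column normalization (columns then sum to 1 within
  1e-9).

## Synthetic data

The generator plants ordered motif tuples at exact category counts (fractions
are rounded to counts once, then assignment is shuffled), with per-sequence
gap lengths drawn uniformly from a range, and variants produced by applying a
fixed mutation record to the members. Two hygiene guarantees make the
manifest exact ground truth:

1. no fragment of a planted motif (any substring as long as the shortest
   planted form) occurs outside the planted spans — this excludes junction
   artifacts, where a random gap base extends a motif into a spurious
   frequent pattern with a strictly larger support set that would otherwise
   invade the closure of the true tuple's combination;
2. variant plantings are redrawn until the canonical maximum-score
   explanation of the planted site equals the planted record (flanking bases
   can otherwise make, say, a substitution explanation exactly as good as the
   intended deletion).

What the generator does **not** emulate: compositional bias and repeats of
real genomes, correlated motif variants, motif occurrences on the reverse
strand, and length variation within a family. Passing the planted-recovery
tests therefore shows correctness of the machinery under the stated model,
not performance on real data.

Default study conditions used by the tests and the acceptance script, chosen
once as representative and kept fixed: the worked-example scenario uses 23
sequences of ~60 nt (16 exact, 7 variant plantings; mining at absolute
support 10, lengths 7–8); the parameter-recovery scenario uses 100 sequences,
two 12-mers, gaps 5–500 nt, planted fraction 0.3 with a quarter of plantings
carrying a single substitution, mined at support ratio 0.2 with lengths
10–12 (long-pattern length restriction as appropriate for heterogeneous
data).

## Degenerate inputs and errors

Empty datasets, thresholds resolving to zero sequences, combination support
below 1, empty profiles (no exact and no approximate placements) and
non-normalizable PSSM columns raise configuration errors rather than
returning silently empty results. Matching failure is a return value
(`None`), not an error. FASTA parsing reports the offending line; alphabet
violations name the record; mutation-record parsing reports the token index.

## Known limitations

* The closure criterion keys on exact support-set equality; a single noisy
  sequence can keep a redundant substring alive. The practical remedy
  (raising the support threshold) is exposed via `MinerConfig`.
* Closed-combination mining is exponential in the worst case; with very low
  thresholds and many short patterns the lattice can blow up. Practical use
  pairs low support ratios with a minimum pattern length (e.g. >10 nt).
* Affine gaps and residue-similarity scoring (needed for serious protein
  work) are not implemented; penalties are per-event constants.
* One approximate record per sequence per tuple is collected; secondary
  approximate placements in the same sequence are ignored by design.
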