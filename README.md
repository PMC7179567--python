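# seqtuples

Feature extraction for nucleic-acid sequence classification based on
**collaborative frequent-subsequence tuples**: ordered groups of gap-less
motifs that co-occur in many sequences, at unbounded distances, each carrying
a profile of its tolerated mutations.

Fixed-width descriptors (k-mers, single PWMs, spaced base pairs) miss two
things that functional sequence families show in practice: motifs of variable
length, and long-range co-occurrence of several motifs whose spacing is not
conserved. `seqtuples` addresses both. It is aimed at people building
classifiers for sequence families (miRNA vs. hairpin background, promoter vs.
non-promoter, binding site vs. flank) who want interpretable features —
each descriptor dimension is a concrete motif tuple you can print, inspect
and export as a PSSM.

## Method

Given a sequence set *S₁ … Sₙ*, the pipeline runs four stages:

1. **Closed frequent substrings.** A prefix-tree walk enumerates every
   substring whose *support* (number of sequences containing it) reaches a
   threshold, within a length band. A substring that is contained in a longer
   retained one occurring in exactly the same sequences is redundant and is
   eliminated (closure); patterns above a configurable length are exempt.
2. **Closed combinations with duplicates.** Sequences × patterns form an
   occurrence-count table. A count of *n* for symbol α is translated to
   presence items {α, 2α, …, nα}, and closed frequent itemsets over those
   items are enumerated with a stack-based depth-first search — closed means
   no strictly larger combination occurs in exactly the same sequences.
3. **Ordered tuples and mutation profiles.** Each combination is re-scanned
   against the sequences: every exact, in-order, non-overlapping placement
   records one observed permutation, and pooled permutation counts become the
   tuple frequencies f(T_j). Re-scanning with approximate matching (an
   edit-event automaton: matches score 0, substitutions/insertions/deletions
   score negative, best-scoring alignment kept, failure below a threshold)
   collects each tuple's *mutation profile*: compact records such as
   `SUB 0 5 U C DEL 1 6 C` with their frequencies f(T_j, r).
4. **Descriptors.** A sequence *Sᵢ* encodes as φ(Sᵢ) = (c(Sᵢ, T₁), …,
   c(Sᵢ, Tₙ)) with

   c(Sᵢ, T_j) = 1 if tuple T_j matches Sᵢ exactly; f(T_j, r) / f(T_j) if it
   matches approximately with an observed mutation record *r* present in the
   profile; 0 otherwise.

   Vectors are written in sparse libsvm format for any downstream learner,
   and profiles can be exported as position-specific scoring matrices.

## Worked example

`examples/feature_descriptors.py` plants the tuple `<GGAGAUG, UGGAGACU>` in a
23-sequence RNA set — 16 sequences verbatim, 7 with the variant
`SUB 0 5 U C DEL 1 6 C` (U→C at position 5 of the first motif, C deleted at
position 6 of the second) — runs the full pipeline, and encodes three query
sequences:

```
profiled tuple: <GGAGAUG, UGGAGACU>
  exact placements: 16
  variant [SUB 0 5 U C DEL 1 6 C]: 7
component for 'exact': 1.0
component for 'variant': 0.4375
component for 'unrelated': 0.0
libsvm lines:
+1 1:1.0
+1 1:0.4375
-1
```

The exact-match query scores 1.0; the variant query's mutation record is in
the profile, so it scores 7/16 = 0.4375; a sequence without the tuple scores
0. `examples/mine_patterns.py` shows pattern and tuple discovery, and
`examples/pssm_export.py` prints the profile as PSSMs — the substitution
appears as a split column (U:16, C:7) at position 5 of the first member.

## Command line

The same pipeline is available as a thin CLI:

```bash
seqtuples simulate data.fa data.json --n 100 --members GGAGAUG,UGGAGACU \
    --exact-fraction 0.7 --seed 1
seqtuples feature-gen data.fa model --min-support 10 --min-len 7 --max-len 8
seqtuples libsvm-gen model.Feature model.FeatureProfile pos.fa neg.fa train.libsvm
seqtuples to-pssm model.Feature model.FeatureProfile motifs.pssm
```

`feature-gen` writes the tuple list (`.Feature`, one tuple per line, members
tab-separated) and the mutation profiles (`.FeatureProfile`, one block per
tuple). Exit codes: 0 success, 2 configuration error, 3 input format error.

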