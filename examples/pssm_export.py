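"""Convert a tuple's mutation profile into position-specific scoring matrices.

Uses a hand-built profile: tuple <GGAGAUG, UGGAGACU> seen 16 times exactly
and 7 times with the record [SUB 0 5 U C, DEL 1 6 C].  The first member's
PSSM shows the substitution as a split column at position 5 (U:16, C:7);
every untouched position accumulates 16 + 7 = 23 counts; the deleted base of
the second member keeps only the 16 exact counts.
"""

from seqtuples import FrequentTuple, MutationProfile, to_pssm

profile = MutationProfile(
    tuple=FrequentTuple(members=("GGAGAUG", "UGGAGACU"), frequency=16),
    exact_frequency=16,
    entries=(("SUB 0 5 U C DEL 1 6 C", 7),),
)

for pssm in to_pssm(profile):
    print(f"member {pssm.member}")
    print("POS " + " ".join(f"{p:>4d}" for p in range(pssm.matrix.shape[1])))
    for i, ch in enumerate(pssm.alphabet):
        print(f"  {ch} " + " ".join(f"{v:4.0f}" for v in pssm.matrix[i]))

print("\ncolumn-normalized frequencies, member 0, position 5:")
norm = to_pssm(profile, normalize=True)[0]
for i, ch in enumerate(norm.alphabet):
    print(f"  {ch}: {norm.matrix[i, 5]:.4f}")
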