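"""Average-mass accounting for the troponin-I C-terminal 27-mer and its
Arg192His variant."""

from pepbiophys import WT_C27, C27_START, PeptideSequence, apply_point_mutation, average_mass

wt = PeptideSequence(WT_C27, C27_START, name="HcTnI-C27")
mut = apply_point_mutation(wt, 192, "H")

print(f"wild-type  {wt.residues}  {average_mass(wt):.2f} Da")
print(f"Arg192His  {mut.residues}  {average_mass(mut):.2f} Da")
print(f"mass difference: {average_mass(wt) - average_mass(mut):.2f} Da")
# The ~19.05 Da gap is exactly the Arg-His residue-mass difference: a single
# conservative substitution, everything else unchanged.
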