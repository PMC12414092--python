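# Published per-residue electrostatic contributions (kcal/mol) to peptide binding.
# The source sentence names four residues (ARG 628, ARG 631, LYS 632, ARG 526) against the
# first three energies; the three values are stored against the first three names, and the
# lower-magnitude trio follows.  ARG 526 therefore appears once, with the second listed value.
residue,e_ele
ARG 628,-49.686
ARG 631,-47.586
LYS 632,-44.579
ARG 526,-34.86
ARG 373,-33.149
ARG 528,-22.995
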