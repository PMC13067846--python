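# Synthetic pistol-ribozyme scaffold (pistolkit bundled default).
# This is a stand-in core designed for testing and demonstration: it has the
# pistol architecture (P2 hairpin, complementary pseudoknot pairs, catalytic
# G/C dinucleotide) but is NOT a crystal-structure or natural sequence.
# All indices below are 1-based positions within `core`.
name: pistol-synthetic-v1
core: GGCAAUAAGGGACUGAAAAGUCCCAAACUAAGCUGCCA
p2_pairs: 9-24,10-23,11-22,12-21,13-20,14-19
pseudoknot_pairs: 1-37,2-36,3-35,4-34
conserved: 1=G,4=A,32=G,33=C
catalytic_g: 32
catalytic_c: 33
numbering: core
default_p1_len: 8
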