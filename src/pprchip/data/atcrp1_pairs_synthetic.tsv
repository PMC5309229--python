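# SYNTHETIC stand-in pair list for the 14 scoring repeats (P1-P14) of AtCRP1.
# The real per-repeat specificity residues come from an annotation figure that
# is not machine-readable; this list was reverse-engineered so that, under the
# packaged default code table, it reproduces the published 14-nt consensus
# UGYNUAGUYYRYUG.  It exercises the pair->PWM->consensus pipeline mechanics
# and must NOT be read as the protein's true residues.
label	res5	resLast
P1	N	D
P2	T	D
P3	N	N
P4	A	D
P5	N	D
P6	T	N
P7	T	D
P8	N	D
P9	N	N
P10	N	T
P11	S	D
P12	N	N
P13	N	D
P14	T	D
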