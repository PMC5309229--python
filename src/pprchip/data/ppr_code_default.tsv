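# Default PPR-code weighting table shipped with pprchip.
# One row per (position-5, last) residue pair of a P-type PPR repeat, with a
# probability vector over the four RNA bases.  Values are this package's own
# transcription of the canonical published pair->base associations
# (T/N->A, T/D->G, S/N->A, N/D->U, N/S->C, N/N->pyrimidine, S/D->purine,
# N/T->pyrimidine, A/D->no preference); the empirical code is degenerate and
# incompletely characterized, so this table is deliberately a swappable input.
res5	resLast	pA	pC	pG	pU
T	N	0.70	0.08	0.14	0.08
T	D	0.08	0.05	0.82	0.05
S	N	0.76	0.08	0.08	0.08
N	D	0.06	0.13	0.06	0.75
N	S	0.08	0.72	0.06	0.14
N	N	0.06	0.50	0.06	0.38
S	D	0.40	0.10	0.40	0.10
N	T	0.07	0.48	0.07	0.38
A	D	0.25	0.25	0.25	0.25
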