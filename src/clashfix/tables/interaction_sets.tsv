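# Published survey: average unsigned errors (kcal/mol) for benchmark sets of
# interacting molecular pairs/ions, per semiempirical method, with set sizes.
# The "All interactions" summary row is not stored; it is recomputed as the
# count-weighted mean of these rows.
dataset	n	PM6-ORG	PM6-D3H4	PM7
S22	22	0.87	0.65	0.76
S12L	12	8.47	10.62	23.63
S66	66	1.00	0.49	0.77
L7	7	5.38	3.92	6.41
X40	40	1.15	1.19	1.83
Ionic H-bonds	15	1.39	1.35	1.44
Repulsive contacts	526	1.70	1.87	2.44
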