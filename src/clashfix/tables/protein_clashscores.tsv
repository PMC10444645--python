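# Published survey: Molprobity clashscores for 21 proteins.
# PDB_report: value from the deposited validation report; PDB: hydrogenated
# original geometry re-analyzed in the survey; remaining columns: geometries
# optimized with each semiempirical method.  Summary rows are not stored;
# column means are recomputed by survey_stats.
protein	PDB_report	PDB	PM6-ORG	PM6-D3H4	PM7
Crambin	0	0.00	6.23	28.04	21.81
Acyl-Coenzyme A	4	5.40	6.08	27.01	20.93
Zinc finger domain of KLF4	2	2.15	5.74	38.74	29.41
Barnase	2	1.18	7.06	32.94	27.06
Zinc endoprotease	2	1.04	8.80	41.95	27.96
Apoptosis inhibitor		7.61	2.00	26.04	26.44
Human hemoglobin, chain A	5	4.22	2.81	33.30	26.27
Flavodoxin	3	4.75	3.89	39.31	31.53
Rab6	9	9.73	3.74	31.45	31.07
Adenylyltransferase	14	12.83	4.29	41.60	31.88
Calcium binding domain	10	11.91	5.16	42.49	36.54
Magnesium loaded ALG-2	1	2.17	3.97	27.43	17.32
Peridinin-chlorophyll	10	8.14	5.43	33.23	31.88
Green Fluorescent Protein	3	9.47	5.96	38.17	34.38
Bacteriorhodopsin	14	12.64	2.67	23.58	29.42
Chymotrypsin	10	9.21	5.61	34.83	28.31
3CLpro	1	2.35	5.77	30.34	28.20
Potassium channel	37	25.92	2.96	23.83	29.40
P450	2	3.12	5.70	33.81	27.38
Sodium channel	8	14.81	0.00	24.53	32.92
Transcobalamin	5	4.69	5.30	28.00	33.91
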